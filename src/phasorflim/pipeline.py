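"""End-to-end orchestration: stacks -> calibrated phasors -> metabolic maps
-> segmentation -> study table -> dynamics report."""
from __future__ import annotations

import pandas as pd

from .io import AcquisitionMeta, DecayStack, Layer
from .phasor import (
    MetabolicMaps,
    PhasorCalibrator,
    metabolic_maps,
    phasor_transform,
    smooth_phasor,
)
from .segment import (
    ClassicalSegmenter,
    UNetSegmenter,
    preprocess,
    roi_statistics,
)
from .synth import (
    IRF,
    DEFAULT_IRF,
    EffectSpec,
    StudyDesign,
    simulate_reference,
    simulate_study,
)

__all__ = ["calibrate_channels", "analyze_stack", "measure_study"]


def calibrate_channels(meta: dict[str, AcquisitionMeta],
                       irf: IRF | None = DEFAULT_IRF,
                       reference: str = "SHG") -> dict[str, PhasorCalibrator]:
    """Fit one calibration per channel from a noise-free reference solution
    simulated with the channel's own acquisition parameters and IRF."""
    cals: dict[str, PhasorCalibrator] = {}
    for chan, m in meta.items():
        ref_meta = AcquisitionMeta(laser_period=m.laser_period, n_bins=m.n_bins,
                                   channel=m.channel)
        ref = simulate_reference(reference, meta=ref_meta, shape=(8, 8),
                                 noiseless=True, irf=irf)
        ph = phasor_transform(ref)[chan]
        from .synth import REFERENCE_TAUS
        cals[chan] = PhasorCalibrator(known_tau=REFERENCE_TAUS[reference]).fit(ph)
    return cals


def analyze_stack(
    stack: DecayStack,
    calibrators: dict[str, PhasorCalibrator],
    smooth_kernel: int = 3,
    smooth_passes: int = 1,
    intensity_threshold: float = 30.0,
    anchor_taus: dict[str, tuple[float, float]] | None = None,
) -> dict[str, MetabolicMaps]:
    """Phasor-transform, calibrate, median-smooth and map one stack."""
    phasors = phasor_transform(stack)
    maps: dict[str, MetabolicMaps] = {}
    for chan, ph in phasors.items():
        ph = calibrators[chan].transform(ph)
        if smooth_passes > 0:
            ph = smooth_phasor(ph, kernel=smooth_kernel, passes=smooth_passes)
        maps[chan] = metabolic_maps(
            ph, anchor_taus=(anchor_taus or {}).get(chan),
            intensity_threshold=intensity_threshold)
    return maps


def measure_study(
    effects: EffectSpec,
    design: StudyDesign,
    seed: int = 0,
    segmenter: UNetSegmenter | ClassicalSegmenter | None = None,
    smooth_kernel: int = 3,
    intensity_threshold: float = 30.0,
) -> pd.DataFrame:
    """Simulate a study and measure it back through the full pipeline.

    Basal-layer acquisitions are reduced to one whole-ROI row per channel;
    dermis acquisitions are single-cell segmented (classical fallback when no
    trained segmenter is supplied) and reduced to one row per cell.  Returns
    the measured study table.
    """
    if segmenter is None:
        segmenter = ClassicalSegmenter()
    calibrators = None
    rows = []
    for acq in simulate_study(effects, design, seed=seed):
        if calibrators is None:
            calibrators = calibrate_channels(acq.stack.meta)
        maps = analyze_stack(acq.stack, calibrators,
                             smooth_kernel=smooth_kernel,
                             intensity_threshold=intensity_threshold)
        layer = acq.stack.meta["NADPH"].layer
        if layer == Layer.basal:
            rows.append(roi_statistics(maps, unit="roi", meta=acq.stack.meta))
        else:
            mm = maps["NADPH"]
            x = preprocess(mm.phasor.intensity, maps["FAD"].phasor.intensity,
                           mm.tau_phi, maps["FAD"].tau_phi)
            mask = segmenter.predict(x)
            rows.append(roi_statistics(maps, mask, unit="cell",
                                       meta=acq.stack.meta))
    return pd.concat(rows, ignore_index=True)
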