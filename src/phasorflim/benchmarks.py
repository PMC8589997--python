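"""Standard synthetic benchmarks: fixed, seeded problem instances used by
the test suite, the CLI and the acceptance script.

Problem sizes are scaled to desk hardware (small fields, reduced arm sizes)
while keeping the acquisition physics and the study structure of the
full-scale defaults; the methods note documents the choices.
"""
from __future__ import annotations

import numpy as np

from .io import Condition, Layer, Timepoint
from .phasor import DEFAULT_ANCHOR_TAUS
from .pipeline import analyze_stack, calibrate_channels
from .segment import MultimodalInput, preprocess
from .synth import (
    BiomarkerModel,
    EffectSpec,
    SceneSpec,
    StudyDesign,
    simulate_stack,
)

__all__ = ["make_segmentation_dataset", "scaled_study_design",
           "default_models"]


def default_models(effects: EffectSpec | None = None) -> dict[str, BiomarkerModel]:
    """Two-channel biomarker models at the baseline bound fractions."""
    effects = effects or EffectSpec()
    return {
        chan: BiomarkerModel(tau_free=DEFAULT_ANCHOR_TAUS[chan][0],
                             tau_bound=DEFAULT_ANCHOR_TAUS[chan][1],
                             f_bound=effects.baseline_f_bound[chan])
        for chan in ("NADPH", "FAD")
    }


def make_segmentation_dataset(
    n_scenes: int,
    image_size: int = 96,
    n_cells: int = 4,
    seed: int = 0,
) -> list[tuple[MultimodalInput, np.ndarray]]:
    """Seeded dermis scenes rendered through the phasor pipeline.

    Each item is (preprocessed 4-plane input, ground-truth label mask); the
    input planes are the NAD(P)H/FAD intensities and phase-lifetime maps the
    segmenter consumes in production.
    """
    models = default_models()
    scene = SceneSpec(layer=Layer.dermis, image_size=image_size,
                      n_cells=n_cells)
    calibrators = None
    dataset = []
    for i in range(n_scenes):
        scene_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0])
        stack, _, labels = simulate_stack(scene, models, seed=scene_seed)
        if calibrators is None:
            calibrators = calibrate_channels(stack.meta)
        maps = analyze_stack(stack, calibrators)
        x = preprocess(maps["NADPH"].phasor.intensity,
                       maps["FAD"].phasor.intensity,
                       maps["NADPH"].tau_phi, maps["FAD"].tau_phi)
        dataset.append((x, labels))
    return dataset


def scaled_study_design(image_size: int = 128) -> StudyDesign:
    """Desk-scale study design with the full arm structure.

    Arms {8, 8, 8, 2} x 3 timepoints x 2 layers x 2 ROIs, 128 px fields —
    a size at which the planted effects remain comfortably detectable while
    a full simulate -> phasor -> segment -> analyze round trip stays within
    a few CPU-minutes.
    """
    return StudyDesign(
        samples_per_arm={
            Condition.control: 8,
            Condition.uva1_25: 8,
            Condition.uva1_40: 8,
            Condition.uva1_40_sunscreen: 2,
        },
        rois_per_layer=2,
        timepoints=[Timepoint.T0, Timepoint.T30min, Timepoint.T2h],
        layers=[Layer.basal, Layer.dermis],
        cells_per_dermis_roi=6,
        basal_cells_per_roi=15,
        image_size=image_size,
    )
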