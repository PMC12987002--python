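"""Desk-scale benchmark studies shared by the test suite and the
reproduction script.

Each study regenerates its phantom inputs, runs the method under test and
returns plain numbers.  Problem sizes are chosen so the full battery runs on
a single CPU in minutes (the methods note documents the scales); every study
is a pure function of its seed arguments.
"""

from __future__ import annotations

import numpy as np

from embryofuse import phantom
from embryofuse.classify import compare_modalities
from embryofuse.fusion_nets import (FusionModelConfig, build_fusion_model,
                                    fuse_neural, mse_loss, train_fusion)
from embryofuse.metrics import average_gradient, mse
from embryofuse.pyramid import build_laplacian, collapse, fuse_lp
from embryofuse.roi import locate_embryo

__all__ = ["reconstruction_study", "fusion_recovery_study", "distillation_study",
           "roi_study", "modality_study"]


def reconstruction_study(n_images: int = 20, size: int = 64, n_levels: int = 4,
                         seed: int = 0) -> float:
    """Worst-case build/collapse round-trip error over seeded random images."""
    worst = 0.0
    for i in range(n_images):
        img = np.random.default_rng(seed * 1000 + i).random((size, size))
        err = np.abs(collapse(build_laplacian(img, n_levels), clip=False) - img).max()
        worst = max(worst, float(err))
    return worst


def fusion_recovery_study(n_scenes: int = 20, image_size: int = 256,
                          seed: int = 0) -> dict:
    """Laplacian fusion vs the best single plane on depth-split phantoms.

    Scenes alternate 2-cell and 4-cell classes (blastomeres always occupy at
    least two distinct depths), and per scene we record the fused-vs-reference
    MSE, the best single-plane MSE, and the fused / best-plane sharpness ratio.
    """
    mse_fused, mse_best_plane, ag_ratios = [], [], []
    for i in range(n_scenes):
        label = ("2cells", "4cells")[i % 2]
        scene = phantom.make_scene(label, image_size, seed * 100 + i)
        stack = phantom.render_stack(scene)
        reference = phantom.render_all_in_focus(scene)
        fused = fuse_lp(stack, 4)
        mse_fused.append(mse(fused, reference))
        mse_best_plane.append(min(mse(p, reference) for p in stack.planes))
        ag_ratios.append(average_gradient(fused)
                         / max(average_gradient(p) for p in stack.planes))
    return {
        "mse_fused": mse_fused,
        "mse_best_plane": mse_best_plane,
        "ag_ratio_fused_vs_best_plane": ag_ratios,
        "n_wins": int(sum(f < b for f, b in zip(mse_fused, mse_best_plane))),
    }


def distillation_study(n: int = 90, image_size: int = 64, epochs: int = 8,
                       data_seed: int = 11, model_seed: int = 0) -> dict:
    """Train UNet-SC to replicate Laplacian fusion and measure fidelity.

    Returns the per-epoch losses, the epoch-1 / final-epoch loss ratio, the
    held-out MSE to the LP target for the trained and untrained model, the
    sharpness ratio of the network output vs its LP target, and the empirical
    irreducible noise floor (MSE between LP fusions of two different noise
    realizations of the same held-out scenes).
    """
    dataset = phantom.make_dataset(n, seed=data_seed, image_size=image_size)
    model = build_fusion_model(FusionModelConfig(variant="SC"), seed=model_seed)
    untrained = build_fusion_model(FusionModelConfig(variant="SC"), seed=model_seed)
    run = train_fusion(model, dataset, epochs=epochs, lr=1e-3, seed=model_seed)

    trained_mse, untrained_mse, ag_ratios, floors = [], [], [], []
    for item in dataset.subset("test"):
        target = fuse_lp(item.stack, 4)
        fused = fuse_neural(model, item.stack)
        trained_mse.append(mse_loss(fused, target))
        untrained_mse.append(mse_loss(fuse_neural(untrained, item.stack), target))
        ag_ratios.append(average_gradient(fused)
                         / max(average_gradient(target), 1e-12))
        if item.scene is not None:
            clean = phantom.render_stack(item.scene, delta_z=item.stack.delta_z,
                                         noise_sigma=0.0)
            floors.append(mse_loss(target, fuse_lp(clean, 4)))
    return {
        "epoch_losses": run.epoch_losses,
        "loss_reduction": run.epoch_losses[0] / run.epoch_losses[-1],
        "trained_mse": float(np.mean(trained_mse)),
        "untrained_mse": float(np.mean(untrained_mse)),
        "ag_ratio_vs_lp": float(np.mean(ag_ratios)),
        "noise_floor": float(np.mean(floors)) if floors else None,
    }


def roi_study(n_per_class: int = 20, image_size: int = 256, seed: int = 0) -> dict:
    """Boundary recovery via coarse detection + radial refinement.

    Runs the full localization chain on fused renders of every embryo-bearing
    class and reports relative radius errors and center errors in pixels.
    """
    radius_errors, center_errors = [], []
    for i in range(n_per_class):
        for label in ("1cell", "2cells", "3cells", "4cells", "more"):
            scene = phantom.make_scene(label, image_size, seed * 100 + i)
            fused = fuse_lp(phantom.render_stack(scene), 4)
            est = locate_embryo(fused)
            radius_errors.append(abs(est.radius - scene.embryo_radius)
                                 / scene.embryo_radius)
            center_errors.append(float(np.hypot(
                est.center[0] - scene.well_center[0],
                est.center[1] - scene.well_center[1])))
    return {
        "median_radius_error": float(np.median(radius_errors)),
        "median_center_error": float(np.median(center_errors)),
        "radius_errors": radius_errors,
        "center_errors": center_errors,
    }


def modality_study(n: int = 500, image_size: int = 96, seeds=(0, 1, 2, 3, 4),
                   epochs: int = 5, data_seed: int = 5,
                   input_size: int = 64) -> dict:
    """Fused vs single-plane-F0 classification on the synthetic benchmark.

    Crops feed the classifier at 64 px: coarser inputs discard the fine
    structure that fusion recovers and with it the very effect under test.
    """
    dataset = phantom.make_dataset(n, seed=data_seed, image_size=image_size)
    rows = compare_modalities(dataset, arch="small_cnn", seeds=seeds,
                              epochs=epochs, input_size=input_size)
    return {
        "rows": [
            {"seed": r.seed, "fused_accuracy": r.fused_accuracy,
             "single_plane_accuracy": r.single_plane_accuracy,
             "difference": r.difference}
            for r in rows
        ],
        "wins": int(sum(r.fused_accuracy >= r.single_plane_accuracy for r in rows)),
        "mean_difference": float(np.mean([r.difference for r in rows])),
    }
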