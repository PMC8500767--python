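"""Seeded desk-scale benchmark experiments.

Each function generates its own synthetic inputs, runs one part of the
screening framework end to end and returns the measured quantities as a
dict.  Shared by the test suite and the acceptance script; all randomness
is controlled by the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .backbone import PatchClassifier, DensityRegressor, train_test_split_indices
from .cells import GaussianKernelSpec, nms_peaks
from .pipeline import ScreenConfig, screen_slide
from .search import exhaustive_scan, mask_fraction_classifier, search
from .sequence import SequenceDensityCounter
from .staging import StagingThresholds
from .synthetic import (LesionSpec, SlideSpec, generate_nuclei_patches,
                        generate_sequence_dataset, generate_slide,
                        generate_tissue_patches, make_staging_spec)


def classifier_benchmark(seed=0, n_patches=200, size=64, epochs=50):
    """Held-out accuracy of the tissue classifier on tumor/normal patches.

    200 synthetic 64x64 patches (100 tumor / 100 normal), 70/30 split,
    trained for at most ``epochs`` epochs on CPU.
    """
    X, y = generate_tissue_patches(n_patches, size=size, seed=seed)
    tr, te = train_test_split_indices(n_patches, 0.70, seed=seed + 1)
    clf = PatchClassifier(base_filters=8, epochs=epochs, batch_size=16,
                          random_state=seed)
    clf.fit(X[tr], y[tr])
    acc = float(np.mean(clf.predict(X[te]) == y[te]))
    return {"accuracy": acc, "n_train": len(tr), "n_test": len(te),
            "epochs": epochs, "final_loss": clf.loss_history_[-1]}


def cell_counting_benchmark(seed=0, n_patches=120, size=64, epochs=60,
                            sigma=3.0):
    """Counting error of the trained cell-level density model.

    Nuclei patches with 4-sigma-separated cells; counting = NMS peaks of the
    predicted density (lightly smoothed to suppress decoder ripple).
    Reports the mean relative absolute counting error on the held-out 30%.
    """
    X, points, Y = generate_nuclei_patches(n_patches, size=size, seed=seed,
                                           sigma=sigma)
    tr, te = train_test_split_indices(n_patches, 0.70, seed=seed + 1)
    reg = DensityRegressor(base_filters=8, epochs=epochs, batch_size=16,
                           random_state=seed)
    reg.fit(X[tr], Y[tr])
    spec = GaussianKernelSpec(sigma=sigma)
    min_height = 0.1 * spec.peak_value()
    rel_errors = []
    int_errors = []
    for i in te:
        dens = reg.predict(X[i][None])[0]
        k_true = len(points[i])
        k_nms = len(nms_peaks(dens, radius=sigma, min_height=min_height,
                              smooth_sigma=1.5))
        rel_errors.append(abs(k_nms - k_true) / k_true)
        int_errors.append(abs(dens.sum() - k_true) / k_true)
    return {"mean_rel_count_error": float(np.mean(rel_errors)),
            "mean_rel_integral_error": float(np.mean(int_errors)),
            "n_train": len(tr), "n_test": len(te), "epochs": epochs,
            "final_loss": reg.loss_history_[-1]}


def lstm_recovery_benchmark(seed=0, n_train=24, n_test=8, seq_len=4, size=64,
                            epochs=80, alpha=2.4e-4, lr_initial=3e-3,
                            lr_final=1e-4):
    """Tumor-mass recovery of the jointly trained channel-FCN + LSTM.

    Held-out mean absolute error of the integrated counts T_i relative to
    the mean ground-truth mass.  The residual weight alpha defaults to the
    gradient-balance value 1/(h*w) (see the methods note); the paper leaves
    alpha to be tuned.
    """
    train_seqs = generate_sequence_dataset(n_train, seq_len, size, seed=seed)
    test_seqs = generate_sequence_dataset(n_test, seq_len, size, seed=seed + 1)
    model = SequenceDensityCounter(base_filters=8, alpha=alpha, epochs=epochs,
                                   lr_initial=lr_initial, lr_final=lr_final,
                                   random_state=seed)
    model.fit(train_seqs)
    abs_err = []
    t0_all = []
    for patches, _gt_maps, gt_counts in test_seqs:
        T = model.predict_counts(patches)
        abs_err.extend(np.abs(T - gt_counts))
        t0_all.extend(gt_counts)
    rel = float(np.mean(abs_err) / np.mean(t0_all))
    return {"relative_count_error": rel, "mean_true_mass": float(np.mean(t0_all)),
            "n_train": n_train, "n_test": n_test, "epochs": epochs}


def _search_test_slide(rng, base=512, n_levels=5):
    """Small slide with 0-2 lesions for search-agreement checks."""
    n_lesions = int(rng.integers(0, 3))
    lesions = []
    for _ in range(n_lesions):
        d_um = float(rng.uniform(20, 120))  # at 1 um/px: 20-120 px lesions
        r = float(rng.uniform(0.35, 0.65) * base)
        c = float(rng.uniform(0.35, 0.65) * base)
        lesions.append(LesionSpec(center=(r, c), diameter_um=d_um,
                                  shape_irregularity=0.3))
    spec = SlideSpec(base_height=base, base_width=base, n_levels=n_levels,
                     pixel_size_um=1.0, lesions=lesions,
                     nuclei_density=400.0,
                     background_seed=int(rng.integers(0, 2 ** 31)))
    return generate_slide(spec, seed=int(rng.integers(0, 2 ** 31)))


def search_agreement_benchmark(seed=0, n_slides=20, patch_size=32, stop_level=1):
    """Quadtree search vs. exhaustive tiling under the mask oracle.

    For each slide, compares the finest-level RoI origin set of the pruned
    quadtree search against a brute-force full scan, and checks the
    classifier-evaluation count against the pruning bound
    ``tiles(start) + 4 * (RoIs above stop_level)``.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    bound_ok = 0
    for _ in range(n_slides):
        slide = _search_test_slide(rng)
        pyr = slide.pyramid
        clf = mask_fraction_classifier(pyr)
        start = pyr.n_levels - 1
        res = search(pyr, clf, t=0.5, start_level=start, stop_level=stop_level,
                     patch_size=patch_size)
        got = {roi.origin for roi in res.rois(stop_level)}
        ref = {roi.origin
               for roi in exhaustive_scan(pyr, clf, 0.5, stop_level, patch_size)}
        if got == ref:
            agree += 1
        h, w = pyr.level_dims(start)
        n_start_tiles = -(-h // patch_size) * (-(-w // patch_size))
        n_above = sum(len(r) for lvl, r in res.rois_by_level.items()
                      if lvl > stop_level)
        if res.n_evaluations <= n_start_tiles + 4 * n_above:
            bound_ok += 1
    return {"agreement": agree, "bound_respected": bound_ok, "n_slides": n_slides}


def staging_oracle_benchmark(seed=0, n_per_class=10, base=3072, n_levels=6):
    """Oracle end-to-end staging accuracy, n_per_class slides per class.

    Slides are generated per class, screened with ground-truth oracle
    detectors (mask-fraction classifier, planted tumor-cell points) and
    staged; reports the per-class and overall agreement with the true
    labels.
    """
    rng = np.random.default_rng(seed)
    cfg = ScreenConfig(patch_size=32, stop_level=1,
                       thresholds=StagingThresholds())
    labels = []
    preds = []
    for cls in ("negative", "itc", "micro", "macro"):
        for _ in range(n_per_class):
            spec = make_staging_spec(cls, rng, base=base, n_levels=n_levels)
            slide = generate_slide(spec, seed=int(rng.integers(0, 2 ** 31)))
            decision, _res, _regions = screen_slide(
                slide.pyramid, None, cfg, slide=slide, oracle=True)
            labels.append(slide.true_label)
            preds.append(decision.label)
    correct = sum(p == t for p, t in zip(preds, labels))
    per_class = {}
    for cls in ("negative", "itc", "micro", "macro"):
        idx = [i for i, t in enumerate(labels) if t == cls]
        per_class[cls] = sum(preds[i] == cls for i in idx)
    return {"correct": correct, "total": len(labels), "per_class": per_class,
            "true_labels": labels, "pred_labels": preds}


def staging_monotonicity_sweep(seed=0, base=3072, n_levels=6,
                               diameters_mm=(0.05, 0.1, 0.15, 0.3, 0.8, 1.5,
                                             2.2, 2.5)):
    """Ordinal staging class along an increasing lesion-diameter sweep.

    The tissue blob is enlarged slightly (radius fraction 0.46) so that the
    largest swept lesion fits inside it for every background draw.
    """
    from .staging import LABEL_ORDER

    rng = np.random.default_rng(seed)
    bg = int(rng.integers(0, 2 ** 31))
    cfg = ScreenConfig(patch_size=32, stop_level=1)
    ordinals = []
    labels = []
    for d_mm in diameters_mm:
        lesion = LesionSpec(center=(base / 2, base / 2), diameter_um=d_mm * 1000,
                            shape_irregularity=0.0)
        spec = SlideSpec(base_height=base, base_width=base, n_levels=n_levels,
                         pixel_size_um=1.0, lesions=[lesion],
                         background_seed=bg, tissue_radius_frac=0.46)
        slide = generate_slide(spec, seed=seed)
        decision, _res, _regions = screen_slide(slide.pyramid, None, cfg,
                                                slide=slide, oracle=True)
        labels.append(decision.label)
        ordinals.append(LABEL_ORDER[decision.label])
    return {"diameters_mm": list(diameters_mm), "labels": labels,
            "ordinals": ordinals,
            "monotone": all(a <= b for a, b in zip(ordinals, ordinals[1:]))}
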