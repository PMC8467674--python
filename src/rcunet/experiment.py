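"""k-fold cross-validation harness over the three architecture variants.

The published protocol: the image set is randomly partitioned into k = 10
test cases; for each fold the remaining images are doubled by augmentation
and used for training; every variant is trained and scored on identical
fold memberships; the summary reports mean +/- standard deviation of the
five metrics across folds (std over fold means, not pooled images) plus the
distribution of JS > 0.75 success counts.

538 images cannot split into ten folds of 54; the partition used is eight
test folds of 54 and two of 53, preserving disjointness and coverage.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .architectures import BackboneConfig, VARIANTS, build_variant
from .evaluation import METRIC_NAMES, evaluate_set
from .preprocess import augment_double
from .training import TrainConfig, train


@dataclass(frozen=True)
class FoldSplit:
    """One fold's train/test index sets within 0..n_images-1."""

    fold: int
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]


def make_folds(n_images: int, k: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Random k-way partition into near-equal test sets (deterministic)."""
    if n_images < k:
        raise ValueError(f"cannot make {k} folds from {n_images} images")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_images)
    chunks = np.array_split(perm, k)
    folds = []
    all_idx = set(range(n_images))
    for f, test in enumerate(chunks):
        test_set = set(int(i) for i in test)
        train_set = sorted(all_idx - test_set)
        folds.append(FoldSplit(fold=f, train_idx=tuple(train_set),
                               test_idx=tuple(sorted(test_set))))
    return folds


def summarize(per_fold: dict[str, list[dict]]) -> pd.DataFrame:
    """Mean/std/median/quartiles of each metric across fold aggregates.

    ``per_fold`` maps variant name to a list of fold-aggregate dicts (the
    second return of :func:`evaluation.evaluate_set`). Std is the sample
    standard deviation across fold means; quartiles use the inclusive-median
    convention.
    """
    rows = []
    for variant, aggs in per_fold.items():
        row: dict = {"variant": variant, "n_folds": len(aggs)}
        for name in METRIC_NAMES:
            vals = [a[name] for a in aggs if a[name] is not None]
            if not vals:
                continue
            row[f"{name}_mean"] = float(np.mean(vals))
            row[f"{name}_std"] = (float(np.std(vals, ddof=1))
                                  if len(vals) > 1 else 0.0)
            row[f"{name}_median"] = float(np.median(vals))
            if len(vals) >= 2:
                q = statistics.quantiles(vals, n=4, method="inclusive")
                row[f"{name}_q1"], _, row[f"{name}_q3"] = q
        successes = [a["success_count"] for a in aggs]
        row["success_mean"] = float(np.mean(successes))
        row["success_median"] = float(np.median(successes))
        rows.append(row)
    if not rows:
        raise ValueError("nothing to summarize")
    return pd.DataFrame(rows)


@dataclass
class CrossvalResult:
    summary: pd.DataFrame
    per_fold: pd.DataFrame
    success_counts: pd.DataFrame
    fold_sizes: list[int]

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out_dir / "summary.csv", index=False)
        self.per_fold.to_csv(out_dir / "per_fold_metrics.csv", index=False)
        self.success_counts.to_csv(out_dir / "success_counts.csv",
                                   index=False)


def run_crossval(dataset, variants=VARIANTS, cfg: TrainConfig | None = None,
                 backbone: BackboneConfig | None = None, k: int = 10,
                 seed: int = 0, threshold: float = 0.5,
                 out_dir=None) -> CrossvalResult:
    """Train and evaluate every variant on identical fold splits.

    ``dataset`` is a list of (image, mask) pairs already at the backbone's
    input extent. Augmentation doubling happens after splitting, on the
    training side only, so no augmented copy of a training image can leak
    into its fold's test set.
    """
    cfg = cfg or TrainConfig()
    backbone = backbone or BackboneConfig()
    dataset = list(dataset)
    folds = make_folds(len(dataset), k=k, seed=seed)

    per_fold_aggs: dict[str, list[dict]] = {v: [] for v in variants}
    rows = []
    for variant in variants:
        for split in folds:
            train_pairs = augment_double([dataset[i] for i in split.train_idx])
            test_pairs = [dataset[i] for i in split.test_idx]
            model = build_variant(variant, backbone)
            fold_cfg = replace(cfg, seed=cfg.seed + split.fold)
            try:
                train(model, train_pairs, fold_cfg)
            except Exception as exc:
                raise RuntimeError(
                    f"training aborted in fold {split.fold} of variant "
                    f"{variant!r}") from exc
            eval_pairs = []
            for img, mask in test_pairs:
                prob = model(np.asarray(img, dtype=np.float64)[None, None])
                eval_pairs.append((mask, prob[0, 0] >= threshold))
            _, agg = evaluate_set(eval_pairs)
            per_fold_aggs[variant].append(agg)
            row = {"variant": variant, "fold": split.fold,
                   "n_test": len(test_pairs),
                   "success_count": agg["success_count"]}
            row.update({m: agg[m] for m in METRIC_NAMES})
            rows.append(row)

    per_fold = pd.DataFrame(rows)
    success = per_fold.pivot(index="fold", columns="variant",
                             values="success_count").reset_index()
    result = CrossvalResult(summary=summarize(per_fold_aggs),
                            per_fold=per_fold, success_counts=success,
                            fold_sizes=[len(f.test_idx) for f in folds])
    if out_dir is not None:
        result.write(out_dir)
    return result
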