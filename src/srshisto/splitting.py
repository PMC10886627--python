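"""Image-level train/validation/test partitioning balanced by class mixture.

Because tissue composition varies strongly between specimens, a uniform
random split of whole images can hand the test set a class mixture far
from the cohort's.  The procedure here draws unassigned images at
random and keeps a draw only if it moves the growing subset's tile-class
distribution closer (in Jensen-Shannon distance) to the full-dataset
distribution; it stops when the subset reaches its target size.  Whole
images are allocated, never individual tiles, so no specimen leaks
across subsets.  A boundary condition requires every class to be present
in every subset; if a filled split violates it the procedure restarts
from a derived seed.

The Jensen-Shannon distance is the square root of the Jensen-Shannon
divergence with base-2 logarithms, a bounded symmetric metric on the
probability simplex: 0 for identical distributions, 1 for disjoint
supports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon

from .annotation import N_CLASSES, TissueClass
from .tiling import TileDataset

__all__ = [
    "class_distribution",
    "jensen_shannon_distance",
    "iterative_split",
    "naive_split",
    "SplitResult",
    "InfeasibleSplitError",
]

DEFAULT_TRAIN_FRAC = 0.8
DEFAULT_VAL_FRAC_OF_TRAIN = 0.1
DEFAULT_STALL_LIMIT = 200
DEFAULT_MAX_RESTARTS = 50


class InfeasibleSplitError(RuntimeError):
    """No split satisfying the every-class-present condition was found."""


def class_distribution(dataset: TileDataset, image_ids=None) -> np.ndarray:
    """Relative tile-class frequencies (length 6, sums to 1).

    Restricted to ``image_ids`` when given; raises if the selection
    contains no tiles.
    """
    tiles = dataset.tiles if image_ids is None else dataset.tiles_for_images(image_ids)
    if not tiles:
        raise ValueError("class distribution undefined: selection contains no tiles")
    counts = np.zeros(N_CLASSES, dtype=np.float64)
    for t in tiles:
        counts[t.label.index] += 1
    return counts / counts.sum()


def jensen_shannon_distance(p, q) -> float:
    """sqrt of the Jensen-Shannon divergence in bits; symmetric, in [0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if np.any(p < 0) or np.any(q < 0) or p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("inputs must be nonnegative with positive mass")
    d = float(jensenshannon(p, q, base=2.0))
    # scipy can return nan for p == q due to a 0/0 in its normalization
    if np.isnan(d):
        return 0.0
    return d


@dataclass
class SplitResult:
    """An image-level partition with its distribution diagnostics."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    distributions: dict[str, list[float]]  # subset name -> length-6 frequencies
    jsd: dict[str, float]  # subset name -> JSD(subset, total)
    seed: int
    n_restarts: int = 0
    config: dict = field(default_factory=dict)

    @property
    def subsets(self) -> dict[str, list[str]]:
        return {"train": self.train_ids, "val": self.val_ids, "test": self.test_ids}

    def to_json(self, path=None) -> str:
        doc = {
            "train_ids": self.train_ids,
            "val_ids": self.val_ids,
            "test_ids": self.test_ids,
            "distributions": self.distributions,
            "jsd": self.jsd,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "config": self.config,
            "class_order": [tc.value for tc in TissueClass],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(str(path), "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "SplitResult":
        with open(str(path)) as fh:
            doc = json.load(fh)
        return cls(
            train_ids=doc["train_ids"],
            val_ids=doc["val_ids"],
            test_ids=doc["test_ids"],
            distributions=doc["distributions"],
            jsd=doc["jsd"],
            seed=doc["seed"],
            n_restarts=doc.get("n_restarts", 0),
            config=doc.get("config", {}),
        )


def _subset_sizes(n_images: int, train_frac: float, val_frac_of_train: float):
    n_test = int(round(n_images * (1.0 - train_frac)))
    n_pool = n_images - n_test  # training pool = train + validation
    n_val = int(round(n_pool * val_frac_of_train))
    n_train = n_pool - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split fractions leave an empty subset for {n_images} images")
    return n_train, n_val, n_test


def _image_class_counts(dataset: TileDataset) -> dict[str, np.ndarray]:
    counts: dict[str, np.ndarray] = {}
    for t in dataset.tiles:
        if t.image_id not in counts:
            counts[t.image_id] = np.zeros(N_CLASSES, dtype=np.float64)
        counts[t.image_id][t.label.index] += 1
    return counts


def _fill_subset(target_size, remaining, counts, total_dist, rng, stall_limit):
    """Grow one subset by JSD-guided random draws.

    Returns ``(ids, trace)`` where each trace entry records the accepted
    JSD and whether the acceptance came from the stall fallback.
    """
    chosen: list[str] = []
    chosen_counts = np.zeros(N_CLASSES, dtype=np.float64)
    trace: list[dict] = []
    current = None  # JSD of the subset so far; None while empty
    stalls = 0
    while len(chosen) < target_size:
        if stalls >= stall_limit:
            # The strict-decrease loop can stall when no single remaining
            # image lowers the JSD; fall back to the best available draw.
            best_id, best_jsd = None, np.inf
            for iid in remaining:
                cand = jensen_shannon_distance(chosen_counts + counts[iid], total_dist)
                if cand < best_jsd:
                    best_id, best_jsd = iid, cand
            pick, cand_jsd, accept, stalled = best_id, best_jsd, True, True
        else:
            pick = remaining[int(rng.integers(len(remaining)))]
            cand_jsd = jensen_shannon_distance(chosen_counts + counts[pick], total_dist)
            # the first image of a subset is always kept; later draws must
            # strictly decrease the distance (ties reject)
            accept, stalled = current is None or cand_jsd < current, False
        if accept:
            chosen.append(pick)
            remaining.remove(pick)
            chosen_counts += counts[pick]
            current = cand_jsd
            trace.append({"jsd": cand_jsd, "stall_accept": stalled})
            stalls = 0
        else:
            stalls += 1
    return chosen, trace


def iterative_split(
    dataset: TileDataset,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    val_frac_of_train: float = DEFAULT_VAL_FRAC_OF_TRAIN,
    seed: int = 0,
    stall_limit: int = DEFAULT_STALL_LIMIT,
    max_restarts: int = DEFAULT_MAX_RESTARTS,
    fill_order: tuple[str, ...] = ("test", "val"),
    return_traces: bool = False,
):
    """Partition images into train/val/test with JSD-balanced mixtures.

    Subsets in ``fill_order`` are filled by the accept/reject procedure;
    the training set receives the remaining images.  With the default
    fractions an 80-image cohort yields a 64-image training pool (of
    which 10%, rounded, becomes validation) and a 16-image test set.

    Deterministic for a fixed dataset and seed.  Raises
    :class:`InfeasibleSplitError` if the every-class-present condition
    cannot be met within ``max_restarts`` reseeded attempts.
    """
    counts = _image_class_counts(dataset)
    all_ids = dataset.image_ids
    n_images = len(all_ids)
    n_train, n_val, n_test = _subset_sizes(n_images, train_frac, val_frac_of_train)
    total_dist = class_distribution(dataset)
    if np.any(np.sum([counts[i] for i in all_ids], axis=0) == 0):
        raise InfeasibleSplitError(
            "a tissue class is absent from the whole cohort; "
            "every class must be present in every subset"
        )
    sizes = {"train": n_train, "val": n_val, "test": n_test}

    for restart in range(max_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, restart]))
        remaining = list(all_ids)
        subsets: dict[str, list[str]] = {}
        traces: dict[str, list[float]] = {}
        for name in fill_order:
            subsets[name], traces[name] = _fill_subset(
                sizes[name], remaining, counts, total_dist, rng, stall_limit
            )
        leftover = [n for n in ("train", "val", "test") if n not in subsets]
        if len(leftover) != 1:
            raise ValueError(f"fill_order must name exactly two of train/val/test: {fill_order}")
        subsets[leftover[0]] = remaining
        traces[leftover[0]] = []

        ok = all(
            np.all(np.sum([counts[i] for i in ids], axis=0) > 0)
            for ids in subsets.values()
        )
        if ok:
            dists = {k: class_distribution(dataset, ids).tolist() for k, ids in subsets.items()}
            jsds = {
                k: jensen_shannon_distance(np.array(v), total_dist)
                for k, v in dists.items()
            }
            result = SplitResult(
                train_ids=subsets["train"],
                val_ids=subsets["val"],
                test_ids=subsets["test"],
                distributions={**dists, "total": total_dist.tolist()},
                jsd=jsds,
                seed=seed,
                n_restarts=restart,
                config={
                    "train_frac": train_frac,
                    "val_frac_of_train": val_frac_of_train,
                    "stall_limit": stall_limit,
                    "fill_order": list(fill_order),
                },
            )
            return (result, traces) if return_traces else result
    raise InfeasibleSplitError(
        f"no split with every class in every subset found in {max_restarts} attempts"
    )


def naive_split(dataset: TileDataset, sizes: tuple[int, int, int], seed: int = 0) -> dict:
    """Uniform random partition into (train, val, test) of the given sizes.

    Baseline for quantifying how much the JSD-guided procedure improves
    subset balance; performs no distribution matching at all.
    """
    rng = np.random.default_rng(seed)
    ids = list(dataset.image_ids)
    if sum(sizes) != len(ids):
        raise ValueError("sizes must sum to the number of images")
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_train, n_val, n_test = sizes
    return {
        "train": perm[:n_train],
        "val": perm[n_train : n_train + n_val],
        "test": perm[n_train + n_val :],
    }
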