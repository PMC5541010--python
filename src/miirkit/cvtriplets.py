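"""Nested cross-validation folds and relative-similarity triplets.

The evaluation scheme is a nested cross-validation: the outer loop leaves
one subject out for testing; the inner loop holds out one presentation
block of every remaining (training) subject for model selection.  With
9 subjects and 5 blocks this yields 45 fold specifications and tests each
of the 540 trials exactly once across the outer folds.

A relative-similarity triplet ``(a, b, c)`` encodes the constraint
"reference trial *a* is more similar to *b* (same class) than to *c*
(different class)".  All three trials of a triplet belong to the same
subject — a single spatial filter cannot be expected to compensate
inter-subject differences, so cross-subject constraints would only add
noise.  Same-class pairs are ordered (both ``(a, b)`` and ``(b, a)`` are
emitted): the reference position is asymmetric, and the resulting counts
are what the enumeration formula below predicts.

For trials of one subject with class sizes ``n_k`` the number of training
triplets is ``sum_k n_k * (n_k - 1) * (N - n_k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import TrialSet

__all__ = [
    "FoldSpec",
    "make_nested_folds",
    "build_training_triplets",
    "build_validation_triplets",
    "triplets_to_tsv",
    "triplets_from_tsv",
]


@dataclass(frozen=True)
class FoldSpec:
    """One inner fold of the nested scheme.

    ``test_ids`` are all trials of the held-out subject; ``validation_ids``
    are the trials of one block from every training subject; ``train_ids``
    are the remaining training-subject trials.  The three sets are pairwise
    disjoint.
    """

    outer_test_subject: str
    inner_validation_block: int
    train_ids: np.ndarray
    validation_ids: np.ndarray
    test_ids: np.ndarray


def make_nested_folds(ts: TrialSet) -> list[FoldSpec]:
    """Enumerate all (outer subject) x (inner block) fold specifications.

    Folds are ordered by subject then block.  Raises if any trial lacks a
    block label.
    """
    meta = ts.metadata()
    if meta["block"].isna().any():
        raise ValueError("every trial needs a block label")
    subjects = sorted(meta["subject"].unique())
    blocks = sorted(meta["block"].unique())
    subj = meta["subject"].to_numpy()
    block = meta["block"].to_numpy()
    ids = meta["trial_id"].to_numpy()
    folds = []
    for s in subjects:
        test = ids[subj == s]
        for b in blocks:
            train = ids[(subj != s) & (block != b)]
            val = ids[(subj != s) & (block == b)]
            folds.append(
                FoldSpec(
                    outer_test_subject=s,
                    inner_validation_block=int(b),
                    train_ids=train,
                    validation_ids=val,
                    test_ids=test,
                )
            )
    return folds


def _as_array(values, ids: np.ndarray) -> np.ndarray:
    """Index labels/subjects (full-length array or mapping) by trial ids."""
    if isinstance(values, Mapping):
        return np.asarray([values[int(i)] for i in ids])
    values = np.asarray(values)
    return values[ids]


def build_training_triplets(train_ids: Sequence[int], labels, subjects) -> np.ndarray:
    """All within-subject training triplets, as an (n, 3) int array.

    ``labels`` and ``subjects`` are full-length per-trial arrays (indexed by
    trial id) or mappings.  Within each subject, every ordered same-class
    pair ``(a, b)``, ``a != b``, is combined with every different-class trial
    ``c`` of that subject.  A class with fewer than two trials for a subject
    simply contributes no pairs.  Output is deterministically sorted.
    """
    train_ids = np.asarray(train_ids)
    lab = _as_array(labels, train_ids)
    sub = _as_array(subjects, train_ids)
    out = []
    for s in np.unique(sub):
        ids_s = train_ids[sub == s]
        lab_s = lab[sub == s]
        for cls in np.unique(lab_s):
            same = ids_s[lab_s == cls]
            other = ids_s[lab_s != cls]
            if same.size < 2 or other.size == 0:
                continue
            a, b = np.meshgrid(same, same, indexing="ij")
            mask = a != b
            pairs = np.stack([a[mask], b[mask]], axis=1)
            n_p, n_o = pairs.shape[0], other.size
            trip = np.empty((n_p * n_o, 3), dtype=np.int64)
            trip[:, :2] = np.repeat(pairs, n_o, axis=0)
            trip[:, 2] = np.tile(other, n_p)
            out.append(trip)
    if not out:
        return np.empty((0, 3), dtype=np.int64)
    trips = np.concatenate(out)
    order = np.lexsort((trips[:, 2], trips[:, 1], trips[:, 0]))
    return trips[order]


def build_validation_triplets(
    validation_ids: Sequence[int], combined_ids: Sequence[int], labels, subjects
) -> np.ndarray:
    """Validation triplets: reference from the validation set, partners from
    the combined training + validation set.

    ``a`` ranges over validation trials; ``b`` over same-subject same-class
    trials of the combined set excluding ``a``; ``c`` over same-subject
    different-class trials of the combined set.  Raises if the validation
    set is not a subset of the combined set.
    """
    validation_ids = np.asarray(validation_ids)
    combined_ids = np.asarray(combined_ids)
    if not np.isin(validation_ids, combined_ids).all():
        raise ValueError("validation ids must be a subset of the combined ids")
    lab_v = _as_array(labels, validation_ids)
    sub_v = _as_array(subjects, validation_ids)
    lab_c = _as_array(labels, combined_ids)
    sub_c = _as_array(subjects, combined_ids)
    out = []
    for a, la, sa in zip(validation_ids, lab_v, sub_v):
        in_subj = sub_c == sa
        b_pool = combined_ids[in_subj & (lab_c == la)]
        b_pool = b_pool[b_pool != a]
        c_pool = combined_ids[in_subj & (lab_c != la)]
        if b_pool.size == 0 or c_pool.size == 0:
            continue
        bb, cc = np.meshgrid(b_pool, c_pool, indexing="ij")
        trip = np.empty((bb.size, 3), dtype=np.int64)
        trip[:, 0] = a
        trip[:, 1] = bb.ravel()
        trip[:, 2] = cc.ravel()
        out.append(trip)
    if not out:
        return np.empty((0, 3), dtype=np.int64)
    trips = np.concatenate(out)
    order = np.lexsort((trips[:, 2], trips[:, 1], trips[:, 0]))
    return trips[order]


def triplets_to_tsv(triplets: np.ndarray, path) -> None:
    np.savetxt(path, triplets, fmt="%d", delimiter="\t", header="a\tb\tc", comments="")


def triplets_from_tsv(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int64, delimiter="\t", skiprows=1).reshape(-1, 3)
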