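"""Scoring clusterings against true labels, and rank-band calibration.

Accuracy matches clusters to species one-to-one (maximum-weight bipartite
matching on the contingency table) and reports the matched fraction in
percent.  The calibration experiment estimates, for every relative rank
position of the sorted difference list, the probability that an
interspecies difference exceeds an intraspecies one — the curve that
motivates retaining only the 60%-80% band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .distance import DistanceParams
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Species x cluster fragment counts."""

    counts: np.ndarray
    species_order: tuple[str, ...]
    cluster_order: tuple[int, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency(assignments: Mapping[str, int],
                labels: Mapping[str, str]) -> ContingencyTable:
    """Cross-tabulate cluster assignments against true species labels.

    Fragments with an assignment but no label are excluded with a warning;
    labels without an assignment are ignored.
    """
    missing = [fid for fid in assignments if fid not in labels]
    if missing:
        logger.warning("%d assigned fragment(s) have no label and are "
                       "excluded from evaluation", len(missing))
    pairs = [(labels[fid], c) for fid, c in assignments.items()
             if fid in labels]
    if not pairs:
        raise InputError("no labeled fragments to evaluate")
    species = tuple(sorted({s for s, _ in pairs}))
    clusters = tuple(sorted({c for _, c in pairs}))
    srow = {s: i for i, s in enumerate(species)}
    ccol = {c: j for j, c in enumerate(clusters)}
    counts = np.zeros((len(species), len(clusters)), dtype=np.int64)
    for s, c in pairs:
        counts[srow[s], ccol[c]] += 1
    return ContingencyTable(counts=counts, species_order=species,
                            cluster_order=clusters)


def accuracy(table: ContingencyTable) -> float:
    """Binning accuracy in percent under optimal one-to-one matching.

    Species and clusters are matched to maximise the number of fragments on
    the matched diagonal; unmatched rows or columns (when the counts
    differ) contribute zero.  The result is
    ``100 * matched / total_fragments``.
    """
    if table.counts.size == 0 or table.total == 0:
        raise InputError("contingency table is empty")
    rows, cols = linear_sum_assignment(table.counts, maximize=True)
    matched = int(table.counts[rows, cols].sum())
    return 100.0 * matched / table.total


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-rank-position probability that the interspecies sorted difference
    exceeds the intraspecies one, estimated from random fragment triples."""

    positions: np.ndarray   # relative rank positions in (0, 1]
    p_values: np.ndarray    # estimated probabilities, one per rank
    n_trials: int
    stderr: np.ndarray      # binomial standard error of each estimate
    level: str | None = None

    def band_mean(self, lower: float, upper: float) -> float:
        """Mean probability over relative positions in (lower, upper]."""
        mask = (self.positions > lower) & (self.positions <= upper)
        if not mask.any():
            raise ParameterError("no rank positions inside the requested band")
        return float(self.p_values[mask].mean())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"position": self.positions,
                             "p": self.p_values, "stderr": self.stderr})


def calibrate_range(features_by_species: Mapping[str, np.ndarray],
                    n_trials: int = 10_000,
                    species_pairs: Sequence[tuple[str, str]] | None = None,
                    params: DistanceParams | None = None,
                    seed: int = 0,
                    ties: str = "half",
                    level: str | None = None) -> CalibrationCurve:
    """Estimate the rank-position calibration curve from fragment triples.

    Each trial samples two fragments A, B from one species and a third C
    from a different species, sorts the absolute feature differences of
    (A, B) and of (A, C), and compares them rank by rank.  The curve value
    at rank ``i`` is the fraction of trials in which the interspecies
    difference D_i(A, C) exceeds the intraspecies difference D_i(A, B).

    Parameters
    ----------
    features_by_species : mapping of species name -> (n_i, m) feature array
        At least two species, each with at least two fragments.
    species_pairs : optional list of (intra_species, other_species)
        Sampling scheme for the triples; by default the intra species and
        the other species are drawn uniformly at each trial.
    ties : {"half", "strict"}
        How rank ties (equal differences) are scored: ``"half"`` counts a
        tie as 1/2 — the unbiased convention, under which a same-species
        null gives exactly 0.5 at every rank in expectation; ``"strict"``
        counts a tie as "not larger".
    """
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    if ties not in ("half", "strict"):
        raise ParameterError(f"ties must be 'half' or 'strict', got {ties!r}")
    names = sorted(features_by_species)
    feats = {s: np.asarray(features_by_species[s], dtype=float) for s in names}
    if len(names) < 2:
        raise InputError("calibration needs at least 2 species")
    dims = {feats[s].shape[1] for s in names}
    if len(dims) != 1:
        raise InputError("species feature matrices have mismatched dimensions")
    for s in names:
        if feats[s].shape[0] < 2:
            raise InputError(f"species {s!r} has fewer than 2 fragments")
    m = dims.pop()
    rng = np.random.default_rng(seed)

    if species_pairs is None:
        intra_idx = rng.integers(len(names), size=n_trials)
        offsets = rng.integers(1, len(names), size=n_trials)
        other_idx = (intra_idx + offsets) % len(names)
        pair_list = [(names[i], names[j])
                     for i, j in zip(intra_idx, other_idx)]
    else:
        for sa, sc in species_pairs:
            if sa == sc:
                raise ParameterError(
                    f"species pair ({sa!r}, {sc!r}) is not interspecies")
            if sa not in feats or sc not in feats:
                raise InputError(f"unknown species in pair ({sa!r}, {sc!r})")
        choice = rng.integers(len(species_pairs), size=n_trials)
        pair_list = [species_pairs[c] for c in choice]

    A = np.empty((n_trials, m))
    B = np.empty((n_trials, m))
    C = np.empty((n_trials, m))
    for t, (sa, sc) in enumerate(pair_list):
        fa = feats[sa]
        ia, ib = rng.choice(fa.shape[0], size=2, replace=False)
        ic = rng.integers(feats[sc].shape[0])
        A[t], B[t], C[t] = fa[ia], fa[ib], feats[sc][ic]

    d_intra = np.sort(np.abs(A - B), axis=1)
    d_inter = np.sort(np.abs(A - C), axis=1)
    wins = (d_inter > d_intra).astype(float)
    if ties == "half":
        wins += 0.5 * (d_inter == d_intra)
    p = wins.mean(axis=0)
    positions = (np.arange(1, m + 1)) / m
    stderr = np.sqrt(np.clip(p * (1 - p), 0, None) / n_trials)
    return CalibrationCurve(positions=positions, p_values=p,
                            n_trials=n_trials, stderr=stderr, level=level)


def group_features_by_label(features, labels: Mapping[str, str]
                            ) -> dict[str, np.ndarray]:
    """Split a FeatureMatrix into per-species row arrays using a label map."""
    groups: dict[str, list[int]] = {}
    for i, fid in enumerate(features.fragment_ids):
        lab = labels.get(fid)
        if lab is None:
            continue
        groups.setdefault(lab, []).append(i)
    if not groups:
        raise InputError("no fragment has a label")
    return {s: features.values[idx] for s, idx in groups.items()}
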