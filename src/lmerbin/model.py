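"""Model/results interface for composition-based binning.

:class:`CompositionBinning` holds the fragment feature matrix and the
distance configuration; its :meth:`~CompositionBinning.fit` runs restarted
k-means and returns a :class:`BinningResults` carrying assignments,
centers, the objective, per-restart diagnostics and a ``summary()`` table.

Example
-------
>>> from lmerbin.simulate import default_two_species_community, build_community
>>> frags, _ = build_community(default_two_species_community(seed=7))
>>> model = CompositionBinning.from_fragments(frags, l=4)
>>> res = model.fit(k=2, restarts=10, seed=0)
>>> res.score({f.id: f.label for f in frags})  # accuracy in percent
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cluster as _cluster
from .distance import DistanceParams, retained_index_range
from .errors import ParameterError
from .kmer import Fragment, FeatureMatrix, build_feature_matrix


class CompositionBinning:
    """Unsupervised binning model over canonical l-mer composition vectors.

    Parameters
    ----------
    features : FeatureMatrix
        n x N(l) matrix of normalised canonical l-mer frequencies.
    band : DistanceParams, optional
        Relative-rank retention band of the modified Chebychev distance
        (default 0.6-0.8).
    """

    def __init__(self, features: FeatureMatrix,
                 band: DistanceParams | None = None):
        self.features = features
        self.band = band if band is not None else DistanceParams()
        # fail early if the band is empty for this dimension
        retained_index_range(features.values.shape[1], self.band)

    @classmethod
    def from_fragments(cls, fragments: Sequence[Fragment], l: int = 4,
                       band: DistanceParams | None = None
                       ) -> "CompositionBinning":
        """Build the model from Fragment objects (features computed here)."""
        return cls(build_feature_matrix(fragments, l=l), band=band)

    @classmethod
    def from_fasta(cls, path, l: int = 4,
                   band: DistanceParams | None = None) -> "CompositionBinning":
        """Build the model from a multi-FASTA file of DNA fragments."""
        from .io import read_fasta
        return cls.from_fragments(read_fasta(path), l=l, band=band)

    @property
    def endog(self) -> np.ndarray:
        """The feature matrix the model clusters (rows = fragments)."""
        return self.features.values

    def fit(self, k: int, restarts: int = 10, max_iter: int = 100,
            seed: int = 0) -> "BinningResults":
        """Cluster the fragments into ``k`` bins.

        Runs k-means ``restarts`` times with seeds ``seed .. seed+restarts-1``
        and keeps the run with the minimum within-cluster band-distance sum.
        """
        if k < 1:
            raise ParameterError(f"k must be >= 1, got {k}")
        runs = [_cluster.kmeans(self.endog, k, params=self.band,
                                max_iter=max_iter, seed=s)
                for s in range(seed, seed + restarts)]
        best = min(runs, key=lambda r: r.objective)  # min is stable: lowest seed
        return BinningResults(model=self, result=best,
                              restart_objectives=tuple(r.objective for r in runs),
                              restart_n_iter=tuple(r.n_iter for r in runs),
                              base_seed=int(seed))


@dataclass(frozen=True)
class BinningResults:
    """Fitted binning: assignments, centers, objective and diagnostics."""

    model: CompositionBinning
    result: _cluster.ClusteringResult
    restart_objectives: tuple[float, ...]
    restart_n_iter: tuple[int, ...]
    base_seed: int
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def assignments(self) -> np.ndarray:
        return self.result.assignments

    @property
    def centers(self) -> np.ndarray:
        return self.result.centers

    @property
    def objective(self) -> float:
        return self.result.objective

    @property
    def k(self) -> int:
        return self.result.k

    def to_frame(self) -> pd.DataFrame:
        """Per-fragment assignments as a two-column DataFrame."""
        return pd.DataFrame({
            "fragment_id": list(self.model.features.fragment_ids),
            "cluster": self.assignments,
        })

    def assignment_map(self) -> dict[str, int]:
        return dict(zip(self.model.features.fragment_ids,
                        (int(c) for c in self.assignments)))

    def score(self, labels: Mapping[str, str]) -> float:
        """Binning accuracy (percent) against true species labels.

        Clusters are matched one-to-one to species by maximum-weight
        bipartite matching on the species x cluster contingency table.
        """
        from .evaluate import accuracy, contingency
        table = contingency(self.assignment_map(), labels)
        return accuracy(table)

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels style."""
        band = self.model.band
        sizes = self.result.cluster_sizes()
        lines = [
            "Composition Binning Results",
            "=" * 46,
            f"{'No. fragments:':<28}{self.model.endog.shape[0]}",
            f"{'Feature dimension N(l):':<28}{self.model.endog.shape[1]}",
            f"{'Clusters (k):':<28}{self.k}",
            f"{'Distance band:':<28}{band.lower:.2f}-{band.upper:.2f}",
            f"{'Restarts:':<28}{len(self.restart_objectives)}",
            f"{'Base seed:':<28}{self.base_seed}",
            f"{'Winning seed:':<28}{self.result.seed}",
            f"{'Iterations (winner):':<28}{self.result.n_iter}",
            f"{'Converged:':<28}{self.result.converged}",
            f"{'Objective:':<28}{self.objective:.6f}",
            "-" * 46,
            f"{'cluster':<10}{'size':>8}",
        ]
        for j, s in enumerate(sizes):
            lines.append(f"{j:<10}{int(s):>8}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def run_summary(self) -> dict:
        """JSON-serialisable provenance record of the fit."""
        band = self.model.band
        return {
            "n_fragments": int(self.model.endog.shape[0]),
            "feature_dimension": int(self.model.endog.shape[1]),
            "l": self.model.features.index.l,
            "k": int(self.k),
            "band_lower": band.lower,
            "band_upper": band.upper,
            "restarts": len(self.restart_objectives),
            "base_seed": self.base_seed,
            "winning_seed": int(self.result.seed),
            "restart_objectives": list(self.restart_objectives),
            "restart_n_iter": list(self.restart_n_iter),
            "objective": float(self.objective),
            "n_iter": int(self.result.n_iter),
            "converged": bool(self.result.converged),
            "cluster_sizes": [int(s) for s in self.result.cluster_sizes()],
            "dropped_fragments": list(self.model.features.dropped_ids),
        }

    def save_assignments(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.run_summary(), fh, indent=2)
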