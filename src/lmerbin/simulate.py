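"""Synthetic metagenomic communities for end-to-end testing.

Species genomes are drawn from first-order Markov chains over the four
nucleotides, so each species has a distinct, internally stable l-mer
distribution whose divergence from other species is controlled by how far
apart the transition matrices are.  Fragments are sampled uniformly from
the genome in random orientation (forward or reverse complement, to
exercise strand collapsing) and substitution errors are injected at a
configurable per-base rate.  The community factors mirror the ones that
matter for composition-based binning: number of species, fragment length,
abundance ratio and error rate.

All randomness flows from explicit seeds; the same configuration always
produces byte-identical FASTA output.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .errors import ParameterError
from .kmer import Fragment, reverse_complement

_BASES = "ACGT"
_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SpeciesModel:
    """First-order Markov model of one species genome.

    ``transition[i, j]`` is P(next = base j | current = base i) with bases
    ordered A, C, G, T; ``initial`` is the distribution of the first base.
    """

    name: str
    transition: np.ndarray
    initial: np.ndarray
    genome_length: int = 500_000

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        p0 = np.asarray(self.initial, dtype=float)
        if t.shape != (4, 4) or p0.shape != (4,):
            raise ParameterError(
                f"species {self.name!r}: transition must be 4x4 and initial "
                f"length 4, got {t.shape} and {p0.shape}")
        if (t < 0).any() or (p0 < 0).any():
            raise ParameterError(
                f"species {self.name!r}: probabilities must be non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError(
                f"species {self.name!r}: transition rows must sum to 1")
        if not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ParameterError(
                f"species {self.name!r}: initial distribution must sum to 1")
        if self.genome_length < 1:
            raise ParameterError(
                f"species {self.name!r}: genome_length must be positive")
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "initial", p0)


@dataclass(frozen=True)
class CommunityConfig:
    """Recipe for one synthetic community.

    ``fragments_per_species`` encodes the relative abundance ratio (e.g.
    (1000, 8000) is a 1:8 community); ``error_rate`` is the per-base
    substitution probability in [0, 0.1].
    """

    species: tuple[SpeciesModel, ...]
    fragments_per_species: tuple[int, ...]
    fragment_length: int = 2000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.fragments_per_species):
            raise ParameterError(
                "species and fragments_per_species lengths differ")
        if not self.species:
            raise ParameterError("community needs at least one species")
        if any(n < 1 for n in self.fragments_per_species):
            raise ParameterError("fragment counts must be positive")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ParameterError(
                f"error_rate must be in [0, 0.1], got {self.error_rate}")
        if self.fragment_length < 1:
            raise ParameterError("fragment_length must be positive")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ParameterError("species names must be unique")

    def to_yaml(self, path) -> None:
        data = {
            "fragment_length": self.fragment_length,
            "error_rate": self.error_rate,
            "seed": self.seed,
            "species": [
                {
                    "name": s.name,
                    "genome_length": s.genome_length,
                    "n_fragments": int(n),
                    "transition": np.asarray(s.transition).tolist(),
                    "initial": np.asarray(s.initial).tolist(),
                }
                for s, n in zip(self.species, self.fragments_per_species)
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunityConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        species, counts = [], []
        for s in data["species"]:
            species.append(SpeciesModel(
                name=s["name"], transition=np.asarray(s["transition"]),
                initial=np.asarray(s["initial"]),
                genome_length=int(s["genome_length"])))
            counts.append(int(s["n_fragments"]))
        return cls(species=tuple(species),
                   fragments_per_species=tuple(counts),
                   fragment_length=int(data["fragment_length"]),
                   error_rate=float(data["error_rate"]),
                   seed=int(data["seed"]))


def synth_genome(model: SpeciesModel, seed: int) -> str:
    """Draw a genome of ``model.genome_length`` bases from the Markov chain."""
    rng = np.random.default_rng(seed)
    L = model.genome_length
    u = rng.random(L).tolist()
    cum_init = np.cumsum(model.initial).tolist()
    cum_rows = [np.cumsum(model.transition[i]).tolist() for i in range(4)]
    out = bytearray(L)
    bases = b"ACGT"
    s = bisect_right(cum_init, u[0])
    s = min(s, 3)
    out[0] = bases[s]
    for i in range(1, L):
        s = bisect_right(cum_rows[s], u[i])
        if s > 3:  # guard against cumsum rounding at exactly 1.0
            s = 3
        out[i] = bases[s]
    return out.decode("ascii")


def sample_fragments(genome: str, n: int, length: int, seed: int,
                     id_prefix: str = "frag",
                     label: str | None = None) -> list[Fragment]:
    """Sample ``n`` fragments of exact ``length`` from uniform start
    positions, each in a random orientation (forward or reverse
    complement with probability 1/2)."""
    if length > len(genome):
        raise ParameterError(
            f"fragment length {length} exceeds genome length {len(genome)}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(genome) - length + 1, size=n)
    flip = rng.random(n) < 0.5
    frags = []
    for i, (st, fl) in enumerate(zip(starts, flip)):
        seq = genome[st:st + length]
        if fl:
            seq = reverse_complement(seq)
        frags.append(Fragment(id=f"{id_prefix}_{i:05d}", sequence=seq,
                              label=label))
    return frags


def inject_errors(fragment: Fragment, rate: float, seed: int) -> Fragment:
    """Substitute each base independently with probability ``rate``.

    A substituted base is replaced by one of the other three bases
    uniformly; length is unchanged.  Only A/C/G/T positions are eligible.
    """
    if not 0.0 <= rate <= 0.1:
        raise ParameterError(f"rate must be in [0, 0.1], got {rate}")
    if rate == 0.0:
        return fragment
    rng = np.random.default_rng(seed)
    raw = np.frombuffer(fragment.sequence.upper().encode("ascii"),
                        dtype=np.uint8).copy()
    code = np.full(raw.shape, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[raw == b] = i
    hit = (rng.random(raw.shape[0]) < rate) & (code != 255)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
        new_code = (code[hit] + shift) % 4
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        raw[hit] = lut[new_code]
    return Fragment(id=fragment.id, sequence=raw.tobytes().decode("ascii"),
                    label=fragment.label)


def build_community(config: CommunityConfig
                    ) -> tuple[list[Fragment], dict[str, str]]:
    """Generate the labeled fragment set and the underlying genomes.

    Per-species fragments are concatenated in config order; counts honour
    ``fragments_per_species`` exactly and everything is deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fragments: list[Fragment] = []
    genomes: dict[str, str] = {}
    for model, n in zip(config.species, config.fragments_per_species):
        g_seed = int(rng.integers(_SEED_MOD))
        f_seed = int(rng.integers(_SEED_MOD))
        e_seed = int(rng.integers(_SEED_MOD))
        genome = synth_genome(model, g_seed)
        genomes[model.name] = genome
        frags = sample_fragments(genome, n, config.fragment_length, f_seed,
                                 id_prefix=model.name, label=model.name)
        if config.error_rate > 0:
            err_rng = np.random.default_rng(e_seed)
            frags = [inject_errors(f, config.error_rate,
                                   int(err_rng.integers(_SEED_MOD)))
                     for f in frags]
        fragments.extend(frags)
    return fragments, genomes


# ---------------------------------------------------------------------------
# Default community: two species of strongly divergent composition
# ---------------------------------------------------------------------------

#: GC-rich species (~65% GC), with state-dependent structure beyond
#: mononucleotide bias so tetramer signatures are informative.
_TRANSITION_GC = np.array([
    [0.20, 0.30, 0.35, 0.15],
    [0.15, 0.35, 0.30, 0.20],
    [0.20, 0.30, 0.35, 0.15],
    [0.10, 0.35, 0.35, 0.20],
])

#: AT-rich species (~32% GC).
_TRANSITION_AT = np.array([
    [0.35, 0.15, 0.15, 0.35],
    [0.30, 0.15, 0.10, 0.45],
    [0.35, 0.20, 0.15, 0.30],
    [0.30, 0.15, 0.15, 0.40],
])

_UNIFORM4 = np.full(4, 0.25)


def default_species_pair(genome_length: int = 500_000
                         ) -> tuple[SpeciesModel, SpeciesModel]:
    """Two species with strongly divergent composition (GC-rich vs
    AT-rich), comparable to genomes separated at order level or above."""
    return (
        SpeciesModel(name="species_gc", transition=_TRANSITION_GC,
                     initial=_UNIFORM4, genome_length=genome_length),
        SpeciesModel(name="species_at", transition=_TRANSITION_AT,
                     initial=_UNIFORM4, genome_length=genome_length),
    )


def default_two_species_community(fragments_per_species: tuple[int, int]
                                  = (2000, 2000),
                                  fragment_length: int = 2000,
                                  error_rate: float = 0.02,
                                  seed: int = 0,
                                  genome_length: int = 500_000
                                  ) -> CommunityConfig:
    """Reference two-species community: 2000 + 2000 fragments of 2000 bp
    at 2% substitution error, from strongly divergent genomes."""
    return CommunityConfig(species=default_species_pair(genome_length),
                           fragments_per_species=tuple(fragments_per_species),
                           fragment_length=fragment_length,
                           error_rate=error_rate, seed=seed)


def interpolated_species_pair(t: float, genome_length: int = 200_000
                              ) -> tuple[SpeciesModel, SpeciesModel]:
    """Species pair whose divergence is dialled by ``t`` in [0, 1]:
    the second transition matrix is ``(1-t)*M_gc + t*M_at``."""
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"t must be in [0, 1], got {t}")
    mixed = (1 - t) * _TRANSITION_GC + t * _TRANSITION_AT
    return (
        SpeciesModel(name="species_gc", transition=_TRANSITION_GC,
                     initial=_UNIFORM4, genome_length=genome_length),
        SpeciesModel(name=f"species_mix_{t:g}", transition=mixed,
                     initial=_UNIFORM4, genome_length=genome_length),
    )


def with_error_rate(config: CommunityConfig, rate: float) -> CommunityConfig:
    """Same community, different substitution error rate."""
    return replace(config, error_rate=rate)
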