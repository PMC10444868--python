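"""Synthetic microsatellite genotype generator.

Provides seed-reproducible multi-locus diploid datasets with known truth for
validating the diversity and calibration machinery: configurable
allele-frequency spectra (explicit or symmetric Dirichlet), inbreeding
(heterozygote deficit Fis), population structure (Balding–Nichols
subpopulation frequencies governed by Fst, which produces the Wahlund
effect when subpopulations are pooled), and i.i.d. genotype missingness.

No mutation-model realism is attempted: the diversity indices are
functionals of allele frequencies only, so allele identity suffices.
Allele codes are emitted as ``100 + 2k`` for a realistic fragment-length
look that round-trips through GENEPOP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import GenotypeMatrix


@dataclass
class SimulationSpec:
    """Generative description of one synthetic microsatellite dataset.

    Parameters
    ----------
    n_individuals, n_loci
        Sample and panel size.
    alleles_per_locus
        Either a single count for every locus or one count per locus.
    freqs
        Optional explicit allele frequencies, one array per locus (each
        summing to 1).  When omitted, ancestral frequencies are drawn from a
        symmetric Dirichlet with the given ``concentration``.
    fis
        Within-population inbreeding coefficient in ``[0, 1)``:
        ``P(hom i) = p_i^2 + fis * p_i (1 - p_i)``,
        ``P(het ij) = 2 p_i p_j (1 - fis)``.
    n_subpops, fst
        If ``n_subpops > 1`` and ``fst > 0``, each subpopulation's
        frequencies are drawn around the ancestral ones from the
        Balding–Nichols distribution ``Dirichlet(p * (1 - Fst) / Fst)``;
        individuals are split evenly across subpopulations.
    missing_rate
        Probability that a whole genotype call is missing, i.i.d.
    """

    n_individuals: int
    n_loci: int
    alleles_per_locus: int | Sequence[int] = 6
    freqs: list[np.ndarray] | None = None
    concentration: float = 1.0
    fis: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    label: str = "simulated"
    locus_prefix: str = "L"

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1:
            raise ValueError("need at least 1 individual and 1 locus")
        if not (0.0 <= self.fis < 1.0):
            raise ValueError("fis must lie in [0, 1)")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if isinstance(self.alleles_per_locus, int):
            counts = [self.alleles_per_locus] * self.n_loci
        else:
            counts = list(self.alleles_per_locus)
            if len(counts) != self.n_loci:
                raise ValueError("alleles_per_locus list must match n_loci")
        if any(k < 1 for k in counts):
            raise ValueError("each locus needs >= 1 allele")
        if self.fis > 0 and all(k == 1 for k in counts):
            raise ValueError("fis > 0 is meaningless with single-allele loci")
        self._allele_counts = counts
        if self.freqs is not None:
            if len(self.freqs) != self.n_loci:
                raise ValueError("freqs must supply one array per locus")
            self.freqs = [np.asarray(f, dtype=float) for f in self.freqs]
            for i, f in enumerate(self.freqs):
                if len(f) != counts[i]:
                    raise ValueError(f"freqs[{i}] length != alleles_per_locus")
                if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
                    raise ValueError(f"freqs[{i}] must be non-negative and sum to 1")

    def to_config(self) -> str:
        """Serialise as a small ``key = value`` config (explicit freqs omitted)."""
        keys = [
            "n_individuals", "n_loci", "concentration", "fis", "n_subpops",
            "fst", "missing_rate", "seed", "label", "locus_prefix",
        ]
        lines = []
        if isinstance(self.alleles_per_locus, int):
            lines.append(f"alleles_per_locus = {self.alleles_per_locus}")
        else:
            lines.append(
                "alleles_per_locus = " + ",".join(map(str, self.alleles_per_locus))
            )
        lines += [f"{k} = {getattr(self, k)}" for k in keys]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, path: str | Path) -> "SimulationSpec":
        """Parse the ``key = value`` config format."""
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in ("n_individuals", "n_loci", "n_subpops", "seed"):
                kwargs[key] = int(val)
            elif key in ("concentration", "fis", "fst", "missing_rate"):
                kwargs[key] = float(val)
            elif key == "alleles_per_locus":
                parts = [int(v) for v in val.split(",")]
                kwargs[key] = parts[0] if len(parts) == 1 else parts
            elif key in ("label", "locus_prefix"):
                kwargs[key] = val
            else:
                raise ValueError(f"line {lineno}: unknown key {key!r}")
        return cls(**kwargs)


def _allele_code(index: int) -> int:
    return 100 + 2 * index


def _draw_ancestral_freqs(spec: SimulationSpec, rng: np.random.Generator) -> list[np.ndarray]:
    if spec.freqs is not None:
        return [f.copy() for f in spec.freqs]
    return [
        rng.dirichlet(np.full(k, spec.concentration)) for k in spec._allele_counts
    ]


def _subpop_freqs(
    p: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    if fst <= 0:
        return p
    # Balding–Nichols: Dirichlet around the ancestral frequencies with
    # concentration (1 - Fst)/Fst
    alpha = p * (1.0 - fst) / fst
    # Dirichlet with any zero alpha is degenerate; nudge to keep it proper
    alpha = np.maximum(alpha, 1e-9)
    return rng.dirichlet(alpha)


def _draw_genotypes(
    p: np.ndarray, n: int, fis: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 2) allele-index pairs with heterozygote deficit ``fis``."""
    out = np.empty((n, 2), dtype=np.int64)
    ibd = rng.random(n) < fis  # both copies identical by descent
    n_ibd = int(ibd.sum())
    if n_ibd:
        a = rng.choice(len(p), size=n_ibd, p=p)
        out[ibd, 0] = a
        out[ibd, 1] = a
    n_free = n - n_ibd
    if n_free:
        out[~ibd] = rng.choice(len(p), size=(n_free, 2), p=p)
    return out


def simulate_population(
    spec: SimulationSpec, return_truth: bool = False
) -> GenotypeMatrix | tuple[GenotypeMatrix, dict]:
    """Draw one population according to the spec; fully seed-reproducible.

    With ``return_truth=True`` also returns the generative truth (ancestral
    and per-subpopulation allele frequencies, fis, fst) for test harnesses.
    """
    rng = np.random.default_rng(spec.seed)
    ancestral = _draw_ancestral_freqs(spec, rng)
    n, L = spec.n_individuals, spec.n_loci
    # even split of individuals across subpopulations
    sub_of = np.repeat(np.arange(spec.n_subpops), -(-n // spec.n_subpops))[:n]
    calls = np.zeros((n, L, 2), dtype=np.int32)
    sub_freqs: list[list[np.ndarray]] = []
    for j in range(L):
        freqs_j = [
            _subpop_freqs(ancestral[j], spec.fst, rng) if spec.n_subpops > 1
            else ancestral[j]
            for _ in range(spec.n_subpops)
        ]
        sub_freqs.append(freqs_j)
        for s in range(spec.n_subpops):
            rows = np.flatnonzero(sub_of == s)
            idx = _draw_genotypes(freqs_j[s], len(rows), spec.fis, rng)
            calls[rows, j, 0] = _allele_code(idx[:, 0])
            calls[rows, j, 1] = _allele_code(idx[:, 1])
    if spec.missing_rate > 0:
        miss = rng.random((n, L)) < spec.missing_rate
        calls[miss] = 0
    width = max(2, len(str(L)))
    g = GenotypeMatrix(
        individual_ids=[f"{spec.label}_{i + 1:04d}" for i in range(n)],
        locus_names=[f"{spec.locus_prefix}{j + 1:0{width}d}" for j in range(L)],
        calls=calls,
        population_label=spec.label,
    )
    if not return_truth:
        return g
    truth = {
        "ancestral_freqs": ancestral,
        "subpop_freqs": sub_freqs,
        "subpop_of_individual": sub_of,
        "fis": spec.fis,
        "fst": spec.fst,
        "expected_he_biased": [1.0 - float(np.sum(p * p)) for p in ancestral],
    }
    return g, truth


def simulate_pair(
    spec: SimulationSpec,
    n_shared: int,
    n_extra_each: int,
    fst_between: float = 0.0,
    n_individuals_2: int | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[str]]:
    """Two populations with partially overlapping marker panels.

    Emulates the cross-study comparison scenario: both populations descend
    from the same ancestral allele-frequency process (optionally diverged
    with ``fst_between`` via Balding–Nichols draws); their panels share
    exactly ``n_shared`` loci and each side carries ``n_extra_each`` private
    loci.  ``spec.n_loci`` is ignored — the panel sizes follow from
    ``n_shared + n_extra_each``.  Returns both matrices plus the shared
    locus names.
    """
    if n_shared < 1:
        raise ValueError("n_shared must be >= 1")
    if n_extra_each < 0:
        raise ValueError("n_extra_each must be >= 0")
    total = n_shared + 2 * n_extra_each
    k = (
        spec.alleles_per_locus
        if isinstance(spec.alleles_per_locus, int)
        else list(spec.alleles_per_locus)
    )
    rng = np.random.default_rng(spec.seed)
    base = SimulationSpec(
        n_individuals=spec.n_individuals,
        n_loci=total,
        alleles_per_locus=k,
        concentration=spec.concentration,
        fis=spec.fis,
        n_subpops=1,
        fst=0.0,
        missing_rate=spec.missing_rate,
        seed=spec.seed,
        label=spec.label,
    )
    ancestral = _draw_ancestral_freqs(base, rng)

    def pop_freqs(sub_rng: np.random.Generator) -> list[np.ndarray]:
        if fst_between <= 0:
            return ancestral
        return [_subpop_freqs(p, fst_between, sub_rng) for p in ancestral]

    shared_names = [f"S{j + 1:02d}" for j in range(n_shared)]
    names1 = shared_names + [f"P1_{j + 1:02d}" for j in range(n_extra_each)]
    names2 = shared_names + [f"P2_{j + 1:02d}" for j in range(n_extra_each)]
    # locus j of pop1 uses ancestral locus j for shared, then the first
    # private bank; pop2 the second bank
    idx1 = list(range(n_shared)) + list(range(n_shared, n_shared + n_extra_each))
    idx2 = list(range(n_shared)) + list(
        range(n_shared + n_extra_each, total)
    )
    sizes = (spec.n_individuals, n_individuals_2 or spec.n_individuals)
    out = []
    for pop, (names, idx, size) in enumerate(
        [(names1, idx1, sizes[0]), (names2, idx2, sizes[1])], start=1
    ):
        freqs = pop_freqs(rng)
        calls = np.zeros((size, len(idx), 2), dtype=np.int32)
        for col, j in enumerate(idx):
            gi = _draw_genotypes(freqs[j], size, spec.fis, rng)
            calls[:, col, 0] = _allele_code(gi[:, 0])
            calls[:, col, 1] = _allele_code(gi[:, 1])
        if spec.missing_rate > 0:
            miss = rng.random((size, len(idx))) < spec.missing_rate
            calls[miss] = 0
        out.append(
            GenotypeMatrix(
                individual_ids=[f"{spec.label}{pop}_{i + 1:04d}" for i in range(size)],
                locus_names=names,
                calls=calls,
                population_label=f"{spec.label}{pop}",
            )
        )
    return out[0], out[1], shared_names
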