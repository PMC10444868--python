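"""Genetic diversity indices, Hardy–Weinberg exact testing and null-allele
screening for microsatellite data.

Per locus the package reports the three classical indices: observed
heterozygosity Ho (fraction of typed individuals that are heterozygous),
expected heterozygosity He (probability that two random gene copies differ,
``1 - sum(p_i^2)``, optionally with Nei's small-sample correction
``2n/(2n-1)``), and allelic diversity A (count of distinct observed alleles;
no rarefaction is applied here — sample-size correction is the job of the
resampling engine in :mod:`msatyard.yardstick`).

Departure from Hardy–Weinberg equilibrium is assessed with an exact test
conditioned on allele counts: for loci with at most two alleles the full
Levene conditional distribution of the heterozygote count is enumerated; for
more alleles a seeded Monte-Carlo permutation of gene copies is used, with
the conditional probability of the genotype table as the ordering statistic.
Per-population p-values are corrected with the Holm–Bonferroni step-down
procedure at alpha = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_HE_ESTIMATORS = ("biased", "unbiased")


@dataclass
class LocusDiversity:
    """Diversity indices at a single locus."""

    locus: str
    n_typed: int
    A: int
    Ho: float
    He: float
    hwe_p: float | None = None
    null_freq: float | None = None


@dataclass
class PopulationDiversity:
    """Across-locus means of the diversity indices with their standard errors.

    The standard error of each index is the sample (n-1) standard deviation
    across loci divided by ``sqrt(L)``; with a single locus it is undefined
    and reported as ``None``.  ``Fis`` is summarised as ``1 - Ho_mean/He_mean``.
    """

    label: str
    N: int
    L: int
    A_mean: float
    He_mean: float
    Ho_mean: float
    A_se: float | None
    He_se: float | None
    Ho_se: float | None
    Fis: float | None
    loci: list[str] | None = None


def _check_estimator(he_estimator: str) -> None:
    if he_estimator not in _HE_ESTIMATORS:
        raise ValueError(f"he_estimator must be one of {_HE_ESTIMATORS}")


def _locus_stats(pairs: np.ndarray, he_estimator: str) -> tuple[int, int, float, float]:
    """(n_typed, A, Ho, He) from an ``(n, 2)`` array of sorted allele pairs."""
    typed = pairs[:, 1] > MISSING
    n = int(typed.sum())
    if n == 0:
        return 0, 0, math.nan, math.nan
    tp = pairs[typed]
    ho = float((tp[:, 0] != tp[:, 1]).mean())
    copies = tp.ravel()
    _, counts = np.unique(copies, return_counts=True)
    a = len(counts)
    p = counts / copies.size
    he = 1.0 - float(np.sum(p * p))
    if he_estimator == "unbiased":
        he *= 2 * n / (2 * n - 1)
    return n, a, ho, he


def locus_diversity(
    g: GenotypeMatrix, locus: str, he_estimator: str = "unbiased"
) -> LocusDiversity:
    """Compute A, Ho and He at one locus from the typed individuals.

    Allele frequencies come from the ``2 * n_typed`` gene copies.  With
    ``he_estimator="unbiased"`` He carries Nei's ``2n/(2n-1)`` correction;
    ``"biased"`` is the plain ``1 - sum(p^2)``.
    """
    _check_estimator(he_estimator)
    j = g.locus_index(locus)
    n, a, ho, he = _locus_stats(g.calls[:, j], he_estimator)
    if n == 0:
        raise ValueError(f"locus {locus!r} has no typed individuals")
    return LocusDiversity(locus=locus, n_typed=n, A=a, Ho=ho, He=he)


def population_summary(
    g: GenotypeMatrix, he_estimator: str = "unbiased", label: str | None = None
) -> PopulationDiversity:
    """Across-locus summary of the population (Table-1 shape: N, A, He, Ho, s.e.).

    Loci with no typed individual are dropped (and logged); at least one
    typable locus is required.
    """
    _check_estimator(he_estimator)
    per_locus = []
    for locus in g.locus_names:
        j = g.locus_index(locus)
        n, a, ho, he = _locus_stats(g.calls[:, j], he_estimator)
        if n == 0:
            logger.warning("locus %r untypable (all missing); dropped", locus)
            continue
        per_locus.append((locus, a, ho, he))
    if not per_locus:
        raise ValueError("all loci untypable")
    loci = [r[0] for r in per_locus]
    A = np.array([r[1] for r in per_locus], dtype=float)
    Ho = np.array([r[2] for r in per_locus])
    He = np.array([r[3] for r in per_locus])
    L = len(loci)

    def se(x: np.ndarray) -> float | None:
        if L < 2:
            return None
        return float(np.std(x, ddof=1) / math.sqrt(L))

    he_mean = float(He.mean())
    ho_mean = float(Ho.mean())
    return PopulationDiversity(
        label=label if label is not None else g.population_label,
        N=g.n_individuals,
        L=L,
        A_mean=float(A.mean()),
        He_mean=he_mean,
        Ho_mean=ho_mean,
        A_se=se(A),
        He_se=se(He),
        Ho_se=se(Ho),
        Fis=(1.0 - ho_mean / he_mean) if he_mean > 0 else None,
        loci=loci,
    )


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact testing
# ---------------------------------------------------------------------------


class HWEResult(NamedTuple):
    p_value: float
    method: str  # "enumeration" | "monte_carlo" | "monomorphic"
    monomorphic: bool


def _levene_distribution(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Levene's conditional distribution of the heterozygote count.

    Given a biallelic locus with fixed allele counts ``n_a + n_b = 2n``, the
    number of heterozygotes h (same parity as ``n_a``) has probability

        P(h) = n! * n_a! * n_b! * 2^h / ( (2n)! * n_aa! * h! * n_bb! )

    with ``n_aa = (n_a - h)/2`` and ``n_bb = (n_b - h)/2``.
    """
    two_n = n_a + n_b
    n = two_n // 2
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    lg = math.lgamma
    const = lg(n + 1) + lg(n_a + 1) + lg(n_b + 1) - lg(two_n + 1)
    logp = np.array(
        [
            const
            + h * math.log(2)
            - lg((n_a - h) // 2 + 1)
            - lg(h + 1)
            - lg((n_b - h) // 2 + 1)
            for h in hs
        ]
    )
    return hs, np.exp(logp)


def biallelic_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value for a 2-allele genotype table.

    Conditional-probability ordering: the p-value sums Levene probabilities
    of every heterozygote count whose probability does not exceed that of
    the observed count.
    """
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    hs, probs = _levene_distribution(n_a, n_b)
    p_obs = probs[np.flatnonzero(hs == n_ab)[0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _table_log_prob_stat(het: int, genotype_counts: np.ndarray) -> float:
    # log conditional probability of a genotype table, up to terms constant
    # under permutation of the fixed pool of gene copies
    return het * math.log(2) - sum(math.lgamma(c + 1) for c in genotype_counts)


def hwe_exact_test(
    g: GenotypeMatrix,
    locus: str,
    n_perm: int = 1000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
) -> HWEResult:
    """Exact test for departure from Hardy–Weinberg equilibrium at one locus.

    Loci with at most two alleles are handled by full enumeration of
    Levene's conditional distribution; loci with more alleles by Monte-Carlo
    permutation of the pooled gene copies (Guo–Thompson-style, with the
    conditional table probability as ordering statistic and the add-one
    estimator ``(1 + #{perm <= obs}) / (n_perm + 1)``).  A monomorphic locus
    admits no testable deviation and returns p = 1 with a flag.
    """
    j = g.locus_index(locus)
    pairs = g.calls[:, j]
    typed = pairs[:, 1] > MISSING
    n = int(typed.sum())
    if n < 2:
        raise ValueError(f"locus {locus!r}: need >= 2 typed individuals, got {n}")
    tp = pairs[typed]
    alleles = np.unique(tp.ravel())
    k = len(alleles)
    if k == 1:
        return HWEResult(1.0, "monomorphic", True)
    if k == 2 and not force_monte_carlo:
        a, b = alleles
        n_ab = int((tp[:, 0] != tp[:, 1]).sum())
        n_aa = int(((tp[:, 0] == a) & (tp[:, 1] == a)).sum())
        n_bb = n - n_ab - n_aa
        return HWEResult(biallelic_exact_p(n_aa, n_ab, n_bb), "enumeration", False)

    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    code = np.searchsorted(alleles, tp)  # (n, 2) allele indices
    obs_het = int((code[:, 0] != code[:, 1]).sum())
    pair_codes = np.minimum(code[:, 0], code[:, 1]) * k + np.maximum(
        code[:, 0], code[:, 1]
    )
    obs_counts = np.bincount(pair_codes, minlength=k * k)
    s_obs = _table_log_prob_stat(obs_het, obs_counts[obs_counts > 0])

    pool = code.ravel().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        pc = pool.reshape(-1, 2)
        het = int((pc[:, 0] != pc[:, 1]).sum())
        codes = np.minimum(pc[:, 0], pc[:, 1]) * k + np.maximum(pc[:, 0], pc[:, 1])
        counts = np.bincount(codes, minlength=k * k)
        s = _table_log_prob_stat(het, counts[counts > 0])
        if s <= s_obs + 1e-9:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return HWEResult(float(p), "monte_carlo", False)


def holm_bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down multiple-test correction; returns reject flags.

    Sequential thresholds ``alpha/(m - k + 1)`` applied to the sorted
    p-values, stopping at the first non-rejection; flags are returned in the
    original input order.
    """
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject


def null_allele_estimate(
    ld: LocusDiversity | tuple[float, float], method: str = "brookfield1"
) -> float:
    """Estimate null-allele frequency from the heterozygote deficit.

    ``brookfield1``: ``r = (He - Ho) / (1 + He)``; ``chakraborty``:
    ``r = (He - Ho) / (He + Ho)``.  Negative estimates (observed excess of
    heterozygotes) are clamped to 0; so is the degenerate He = Ho = 0 case.
    """
    if isinstance(ld, LocusDiversity):
        he, ho = ld.He, ld.Ho
    else:
        he, ho = ld
    if method == "brookfield1":
        r = (he - ho) / (1.0 + he)
    elif method == "chakraborty":
        if he + ho == 0:
            return 0.0
        r = (he - ho) / (he + ho)
    else:
        raise ValueError(f"unknown method {method!r}")
    return max(0.0, float(r))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def locus_report(
    g: GenotypeMatrix,
    he_estimator: str = "unbiased",
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    null_method: str = "brookfield1",
) -> pd.DataFrame:
    """Per-locus table: n_typed, A, Ho, He, HWE p, Holm flag, null frequency.

    HWE p-values are corrected jointly across the population's loci with
    Holm–Bonferroni at ``alpha``.  Loci are flagged, never auto-excluded;
    dropping a locus (e.g. for suspected null alleles) is the caller's call.
    """
    rows = []
    for i, locus in enumerate(g.locus_names):
        ld = locus_diversity(g, locus, he_estimator)
        locus_seed = None if seed is None else seed + i
        if ld.n_typed >= 2:
            hwe = hwe_exact_test(g, locus, n_perm=n_perm, seed=locus_seed)
            p = hwe.p_value
        else:
            p = math.nan
        rows.append(
            {
                "locus": locus,
                "n_typed": ld.n_typed,
                "A": ld.A,
                "Ho": ld.Ho,
                "He": ld.He,
                "hwe_p": p,
                "null_freq": null_allele_estimate(ld, null_method),
            }
        )
    df = pd.DataFrame(rows)
    ok = df["hwe_p"].notna()
    flags = np.zeros(len(df), dtype=bool)
    if ok.any():
        flags[ok.to_numpy()] = holm_bonferroni(df.loc[ok, "hwe_p"], alpha=alpha)
    df.insert(6, "holm_reject", flags)
    return df


def write_reports(
    g: GenotypeMatrix,
    out_locus: str,
    out_population: str,
    he_estimator: str = "unbiased",
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, PopulationDiversity]:
    """Write the per-locus and per-population TSV reports."""
    df = locus_report(g, he_estimator=he_estimator, n_perm=n_perm, seed=seed, alpha=alpha)
    df.to_csv(out_locus, sep="\t", index=False)
    summary = population_summary(g, he_estimator=he_estimator)
    pd.DataFrame(
        [
            {
                "population": summary.label,
                "N": summary.N,
                "L": summary.L,
                "A_mean": summary.A_mean,
                "A_se": summary.A_se,
                "He_mean": summary.He_mean,
                "He_se": summary.He_se,
                "Ho_mean": summary.Ho_mean,
                "Ho_se": summary.Ho_se,
                "Fis": summary.Fis,
            }
        ]
    ).to_csv(out_population, sep="\t", index=False)
    return df, summary
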