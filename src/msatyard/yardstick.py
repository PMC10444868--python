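"""The yardstick calibration engine.

Microsatellite diversity indices printed in different studies are not
directly comparable: marker panels differ, and allelic richness in
particular is strongly sample-size dependent.  The yardstick method fixes a
single well-characterised reference population and compares every other
population to it using only the loci the two share, equalising sample sizes
by resampling individuals with replacement (~1000 replicates) from the
larger sample down to the smaller one.

Two ratio indices result, with the reference in the denominator:

    Her = He_target(shared) / He_reference(shared baseline)
    Art = A_target(shared)  / A_reference(shared baseline)

Multiplying the ratios back by the reference's *full-panel* values yields
calibrated indices on the familiar scale of He and A:

    Hec = Her * He_ref_full        Ac = Art * A_ref_full

and the calibrated observed heterozygosity keeps the target's original
full-data heterozygosity structure:

    Hoc = Hec * (Ho / He)   (ratio from the target's own full locus panel)

When the target's sample size meets or exceeds the reference's, the
published indices are compared directly on the shared loci, without
resampling.  Confidence intervals are the usual normal ones,
``estimate +/- 1.96 * s.e.``; ratio standard errors combine the resampled
side's Monte-Carlo sd with the fixed side's across-locus s.e. by the
first-order delta method.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Union

import numpy as np

from .diversity import PopulationDiversity, _locus_stats, population_summary
from .genotype_io import GenotypeMatrix, ReferencePopulation, subset

logger = logging.getLogger(__name__)

#: Fewest shared loci observed in practice before comparisons get fragile.
DEFAULT_MIN_SHARED = 4


@dataclass
class PublishedPopulation:
    """A population known only through printed diversity indices.

    ``per_locus`` maps locus name to a dict with any subset of the keys
    ``"A"``, ``"He"``, ``"Ho"``; studies that only report population means
    use ``mean_only`` instead.  ``ho_over_he`` is the observed/expected
    heterozygosity ratio of the *original full-panel* data; when absent it
    is derived from the available means if both are present.
    """

    study_id: str
    label: str
    N: int
    per_locus: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_only: dict[str, float] | None = None
    ho_over_he: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"{self.study_id}/{self.label}: N must be >= 1")
        if not self.per_locus and self.mean_only is None:
            raise ValueError(
                f"{self.study_id}/{self.label}: need per_locus or mean_only indices"
            )
        for locus, idx in self.per_locus.items():
            _validate_indices(idx, f"{self.study_id}/{self.label}/{locus}")
        if self.mean_only is not None:
            _validate_indices(self.mean_only, f"{self.study_id}/{self.label}")

    @property
    def locus_names(self) -> list[str]:
        return list(self.per_locus)

    def original_ho_over_he(self) -> float | None:
        """Ho/He from the study's own full data, preferring an explicit value."""
        if self.ho_over_he is not None:
            return self.ho_over_he
        ho = he = None
        if self.mean_only and "Ho" in self.mean_only and "He" in self.mean_only:
            ho, he = self.mean_only["Ho"], self.mean_only["He"]
        elif self.per_locus:
            hos = [v["Ho"] for v in self.per_locus.values() if "Ho" in v]
            hes = [v["He"] for v in self.per_locus.values() if "He" in v]
            if hos and hes:
                ho, he = float(np.mean(hos)), float(np.mean(hes))
        if ho is None or he is None or he == 0:
            return None
        return ho / he


def _validate_indices(idx: Mapping[str, float], where: str) -> None:
    for key, val in idx.items():
        if key in ("He", "Ho") and not (0.0 <= val <= 1.0):
            raise ValueError(f"{where}: {key}={val} outside [0, 1]")
        if key == "A" and val < 1:
            raise ValueError(f"{where}: A={val} < 1")


Target = Union[GenotypeMatrix, PublishedPopulation]


@dataclass
class ResamplingDistribution:
    """Across-locus mean A/He/Ho for each with-replacement subsample."""

    loci: list[str]
    n_sub: int
    n_rep: int
    seed: int
    a: np.ndarray
    he: np.ndarray
    ho: np.ndarray

    @property
    def mean_a(self) -> float:
        return float(self.a.mean())

    @property
    def mean_he(self) -> float:
        return float(self.he.mean())

    @property
    def mean_ho(self) -> float:
        return float(self.ho.mean())

    def sd(self, which: str) -> float:
        x = getattr(self, which)
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


@dataclass
class YardstickResult:
    """One calibrated comparison of a target population against the reference."""

    target_label: str
    reference_label: str
    shared_loci: list[str]
    n_shared: int
    mode: str  # "resample_reference" | "resample_target" | "direct"
    n_replicates: int
    seed: int | None
    her: float
    her_se: float
    art: float | None
    art_se: float | None
    hec: float
    hec_se: float
    ac: float | None
    ac_se: float | None
    hoc: float | None
    hoc_se: float | None
    target_he_shared: float
    target_a_shared: float | None
    target_ho_shared: float | None
    ref_he_baseline: float
    ref_a_baseline: float
    ho_over_he: float | None
    flags: list[str] = field(default_factory=list)

    def ci(self, which: str) -> tuple[float, float] | None:
        est = getattr(self, which)
        se = getattr(self, f"{which}_se")
        if est is None or se is None:
            return None
        return confidence_interval(est, se)

    def to_dict(self) -> dict:
        d = asdict(self)
        for which in ("her", "art", "hec", "ac", "hoc"):
            ci = self.ci(which)
            d[f"{which}_ci_low"] = ci[0] if ci else None
            d[f"{which}_ci_high"] = ci[1] if ci else None
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def shared_loci(
    ref: ReferencePopulation | GenotypeMatrix,
    target: Target,
    aliases: Mapping[str, str] | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> list[str]:
    """Case-sensitive locus intersection in reference order.

    ``aliases`` maps target-side names to reference names (e.g.
    ``{"FH 2004": "FH2004"}``); matching is otherwise exact — a silently
    fuzzy match would be worse than an error.  An empty intersection raises;
    fewer than ``min_shared`` shared loci triggers a warning but the list is
    still returned.
    """
    ref_g = ref.genotypes if isinstance(ref, ReferencePopulation) else ref
    ref_names = ref_g.locus_names
    target_names = target.locus_names
    aliases = aliases or {}
    normalized = {aliases.get(n, n) for n in target_names}
    out = [n for n in ref_names if n in normalized]
    if not out:
        raise ValueError(
            "no shared markers between reference "
            f"{ref_names} and target {list(target_names)}"
        )
    if len(out) < min_shared:
        warnings.warn(
            f"only {len(out)} shared loci (fewer than {min_shared}); "
            "calibration will be imprecise",
            stacklevel=2,
        )
    return out


def resample_indices(
    g: GenotypeMatrix,
    loci: Sequence[str],
    n_sub: int,
    n_rep: int,
    seed: int,
    he_estimator: str = "unbiased",
) -> ResamplingDistribution:
    """Bootstrap-style sample-size correction of the diversity indices.

    Each replicate draws ``n_sub`` individuals *with replacement* and
    computes the across-locus means of A, He and Ho on ``loci``.  A locus
    with no typed individual in some replicate is dropped for that replicate
    (and logged).  The replicate triples and their means/sds summarise what
    the indices would look like at sample size ``n_sub``.
    """
    if n_sub < 2:
        raise ValueError("n_sub must be >= 2")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    gs = subset(g, loci=list(loci))
    rng = np.random.default_rng(seed)
    L = gs.n_loci
    a_out = np.empty(n_rep)
    he_out = np.empty(n_rep)
    ho_out = np.empty(n_rep)
    n_dropped = 0
    for r in range(n_rep):
        rows = rng.integers(0, gs.n_individuals, size=n_sub)
        calls = gs.calls[rows]
        a_vals, he_vals, ho_vals = [], [], []
        for j in range(L):
            n, a, ho, he = _locus_stats(calls[:, j], he_estimator)
            if n == 0:
                n_dropped += 1
                continue
            a_vals.append(a)
            he_vals.append(he)
            ho_vals.append(ho)
        if not a_vals:
            raise ValueError("all loci untypable in a replicate")
        a_out[r] = np.mean(a_vals)
        he_out[r] = np.mean(he_vals)
        ho_out[r] = np.mean(ho_vals)
    if n_dropped:
        logger.warning(
            "%d locus-replicate(s) dropped (no typed individuals in subsample)",
            n_dropped,
        )
    return ResamplingDistribution(
        loci=list(loci), n_sub=n_sub, n_rep=n_rep, seed=seed,
        a=a_out, he=he_out, ho=ho_out,
    )


def calibrate(
    her: float, art: float | None, ref_full: PopulationDiversity
) -> tuple[float, float | None]:
    """Rescale the ratio indices by the reference's full-panel values."""
    if her < 0 or (art is not None and art < 0):
        raise ValueError("ratio indices must be non-negative")
    hec = her * ref_full.He_mean
    ac = None if art is None else art * ref_full.A_mean
    return hec, ac


def confidence_interval(estimate: float, se: float) -> tuple[float, float]:
    """Normal 95% interval, ``estimate +/- 1.96 * s.e.``."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return (estimate - 1.96 * se, estimate + 1.96 * se)


def _point_side(
    g: GenotypeMatrix, loci: Sequence[str], he_estimator: str
) -> tuple[dict[str, float], dict[str, float]]:
    """Across-locus means and s.e. of A/He/Ho on the given loci."""
    s = population_summary(subset(g, loci=list(loci)), he_estimator=he_estimator)
    vals = {"A": s.A_mean, "He": s.He_mean, "Ho": s.Ho_mean}
    ses = {
        "A": s.A_se or 0.0,
        "He": s.He_se or 0.0,
        "Ho": s.Ho_se or 0.0,
    }
    return vals, ses


def _published_side(
    pub: PublishedPopulation, loci: Sequence[str]
) -> tuple[dict[str, float | None], dict[str, float], list[str]]:
    """Unweighted across-locus means of the published per-locus indices.

    Falls back to the study's population means (treated as point values
    with zero s.e.) when no per-locus record exists.
    """
    flags: list[str] = []
    vals: dict[str, float | None] = {}
    ses: dict[str, float] = {}
    if pub.per_locus:
        for key in ("A", "He", "Ho"):
            xs = [
                pub.per_locus[n][key]
                for n in loci
                if n in pub.per_locus and key in pub.per_locus[n]
            ]
            if not xs:
                vals[key] = None
                ses[key] = 0.0
                continue
            vals[key] = float(np.mean(xs))
            ses[key] = (
                float(np.std(xs, ddof=1) / math.sqrt(len(xs))) if len(xs) > 1 else 0.0
            )
    else:
        assert pub.mean_only is not None
        for key in ("A", "He", "Ho"):
            vals[key] = pub.mean_only.get(key)
            ses[key] = 0.0
        flags.append("population-mean indices used (no per-locus values)")
    return vals, ses, flags


def _ratio_se(x_t: float, se_t: float, x_r: float, se_r: float) -> float:
    # delta method for R = x_t / x_r with independent numerator/denominator
    if x_r == 0:
        return math.nan
    return math.sqrt(se_t**2 / x_r**2 + x_t**2 * se_r**2 / x_r**4)


def yardstick_compare(
    ref: ReferencePopulation,
    target: Target,
    n_rep: int = 1000,
    seed: int | None = None,
    he_estimator: str = "unbiased",
    aliases: Mapping[str, str] | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> YardstickResult:
    """Compare a target population against the reference on their shared loci.

    Mode selection follows the sample sizes: with genotypes on both sides
    the larger sample is resampled down to the smaller one's N (ties are
    compared directly); a published target smaller than the reference has
    the *reference* resampled down to its N; a published target at least as
    large as the reference is compared directly, without resampling.

    The reference's full-panel values (computed once over all its loci) are
    the calibration scale; the Ho/He ratio entering Hoc always comes from
    the target's original full data, never the shared subset.
    """
    flags_pre: list[str] = []
    if isinstance(target, PublishedPopulation) and not target.per_locus:
        # mean-only study: its panel is unknown, so the reference's full
        # panel serves as the baseline
        loci = list(ref.genotypes.locus_names)
        flags_pre.append("study panel unknown; reference full panel used as baseline")
    else:
        loci = shared_loci(ref, target, aliases=aliases, min_shared=min_shared)
    alias_back = {v: k for k, v in (aliases or {}).items()}
    n_ref = ref.genotypes.n_individuals
    ref_full: PopulationDiversity = ref.full_panel_summary
    flags: list[str] = flags_pre

    if isinstance(target, GenotypeMatrix):
        target_loci = [alias_back.get(n, n) for n in loci]
        n_t = target.n_individuals
        t_full = population_summary(target, he_estimator=he_estimator)
        ho_over_he = (
            t_full.Ho_mean / t_full.He_mean if t_full.He_mean > 0 else None
        )
        if n_t == n_ref:
            mode = "direct"
            t_vals, t_ses = _point_side(target, target_loci, he_estimator)
            r_vals, r_ses = _point_side(ref.genotypes, loci, he_estimator)
            n_replicates = 0
        elif n_t < n_ref:
            mode = "resample_reference"
            if seed is None:
                raise ValueError("seed is required when resampling")
            dist = resample_indices(
                ref.genotypes, loci, n_sub=n_t, n_rep=n_rep, seed=seed,
                he_estimator=he_estimator,
            )
            r_vals = {"A": dist.mean_a, "He": dist.mean_he, "Ho": dist.mean_ho}
            r_ses = {"A": dist.sd("a"), "He": dist.sd("he"), "Ho": dist.sd("ho")}
            t_vals, t_ses = _point_side(target, target_loci, he_estimator)
            n_replicates = n_rep
        else:
            mode = "resample_target"
            if seed is None:
                raise ValueError("seed is required when resampling")
            dist = resample_indices(
                target, target_loci, n_sub=n_ref, n_rep=n_rep, seed=seed,
                he_estimator=he_estimator,
            )
            t_vals = {"A": dist.mean_a, "He": dist.mean_he, "Ho": dist.mean_ho}
            t_ses = {"A": dist.sd("a"), "He": dist.sd("he"), "Ho": dist.sd("ho")}
            r_vals, r_ses = _point_side(ref.genotypes, loci, he_estimator)
            n_replicates = n_rep
        target_label = target.population_label
        n_t_label = n_t
    else:
        pub_loci = [alias_back.get(n, n) for n in loci]
        t_vals, t_ses, pflags = _published_side(target, pub_loci)
        flags.extend(pflags)
        ho_over_he = target.original_ho_over_he()
        if target.N < n_ref:
            mode = "resample_reference"
            if seed is None:
                raise ValueError("seed is required when resampling")
            dist = resample_indices(
                ref.genotypes, loci, n_sub=target.N, n_rep=n_rep, seed=seed,
                he_estimator=he_estimator,
            )
            r_vals = {"A": dist.mean_a, "He": dist.mean_he, "Ho": dist.mean_ho}
            r_ses = {"A": dist.sd("a"), "He": dist.sd("he"), "Ho": dist.sd("ho")}
            n_replicates = n_rep
        else:
            mode = "direct"
            r_vals, r_ses = _point_side(ref.genotypes, loci, he_estimator)
            n_replicates = 0
        target_label = target.label
        n_t_label = target.N

    if t_vals.get("He") is None:
        raise ValueError(f"target {target_label!r} reports no He on the shared loci")

    her = t_vals["He"] / r_vals["He"]
    her_se = _ratio_se(t_vals["He"], t_ses["He"], r_vals["He"], r_ses["He"])
    if t_vals.get("A") is None:
        art = art_se = None
        flags.append("calibrated allelic richness unavailable: no per-locus A reported")
    else:
        art = t_vals["A"] / r_vals["A"]
        art_se = _ratio_se(t_vals["A"], t_ses["A"], r_vals["A"], r_ses["A"])

    hec, ac = calibrate(her, art, ref_full)
    hec_se = her_se * ref_full.He_mean
    ac_se = None if art_se is None else art_se * ref_full.A_mean
    if ho_over_he is None:
        hoc = hoc_se = None
        flags.append("calibrated observed heterozygosity unavailable: no Ho/He ratio")
    else:
        hoc = hec * ho_over_he
        hoc_se = hec_se * ho_over_he

    logger.info(
        "yardstick: %s vs %s — mode=%s, n_shared=%d, N_target=%s, seed=%s",
        target_label, ref.label, mode, len(loci), n_t_label, seed,
    )
    return YardstickResult(
        target_label=target_label,
        reference_label=ref.label,
        shared_loci=loci,
        n_shared=len(loci),
        mode=mode,
        n_replicates=n_replicates,
        seed=seed,
        her=float(her),
        her_se=float(her_se),
        art=None if art is None else float(art),
        art_se=None if art_se is None else float(art_se),
        hec=float(hec),
        hec_se=float(hec_se),
        ac=None if ac is None else float(ac),
        ac_se=None if ac_se is None else float(ac_se),
        hoc=None if hoc is None else float(hoc),
        hoc_se=None if hoc_se is None else float(hoc_se),
        target_he_shared=float(t_vals["He"]),
        target_a_shared=None if t_vals.get("A") is None else float(t_vals["A"]),
        target_ho_shared=None if t_vals.get("Ho") is None else float(t_vals["Ho"]),
        ref_he_baseline=float(r_vals["He"]),
        ref_a_baseline=float(r_vals["A"]),
        ho_over_he=None if ho_over_he is None else float(ho_over_he),
        flags=flags,
    )
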