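"""Reading, writing and subsetting diploid microsatellite genotype data.

The raw currency of the package is the :class:`GenotypeMatrix`: individuals
by loci, each cell an unordered pair of integer allele codes (conventionally
fragment lengths) or missing.  Two plain-text exchange formats are supported:
GENEPOP (2- or 3-digit allele coding, ``0``-coded missing alleles) and a
simple tabular CSV/TSV dialect with either one joined column per locus
(``"141/143"``) or two columns per locus (``"L1.a1"``, ``"L1.a2"``).

A genotype with exactly one missing allele carries no usable information for
heterozygosity or allele counting under a complete-diploid model, so parsers
coerce such half-calls to fully missing and log the coercion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel allele code for a missing gene copy.
MISSING = 0


class GenotypeParseError(ValueError):
    """Malformed genotype input (carries a line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for one population: individuals x loci x 2 alleles.

    Parameters
    ----------
    individual_ids
        Unique sample identifiers, one per row.
    locus_names
        Unique marker names, one per column.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Allele codes
        are positive integers; ``(0, 0)`` marks a missing genotype.  Pairs
        are stored sorted (phase is meaningless for microsatellites), so
        ``(141, 143)`` and ``(143, 141)`` compare equal.
    population_label
        Free-form label for the population the sample represents.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray
    population_label: str = ""

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_names = [str(n) for n in self.locus_names]
        calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.locus_names)
        if n < 1 or L < 1:
            raise ValueError("need at least 1 individual and 1 locus")
        if calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({n} individuals, {L} loci, 2)"
            )
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids are not unique")
        if len(set(self.locus_names)) != L:
            raise ValueError("locus_names are not unique")
        if (calls < 0).any():
            raise ValueError("negative allele codes are not allowed")
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(
                "half-called genotype (one allele missing) at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_names[j]!r}; "
                "coerce to missing before constructing a GenotypeMatrix"
            )
        calls = np.sort(calls, axis=2)
        self.calls = calls

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask of complete (non-missing) genotypes."""
        return self.calls[:, :, 1] > MISSING

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )


def subset(
    g: GenotypeMatrix,
    individuals: Sequence[str] | None = None,
    loci: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Order-preserving restriction to the requested individuals and/or loci.

    The order of the returned rows/columns follows the order of the request,
    allowing callers to reorder as well as restrict.  Unknown names raise a
    ``KeyError`` listing every offender.
    """
    if individuals is None:
        row_idx = np.arange(g.n_individuals)
        ids = list(g.individual_ids)
    else:
        pos = {v: i for i, v in enumerate(g.individual_ids)}
        unknown = [i for i in individuals if i not in pos]
        if unknown:
            raise KeyError(f"unknown individuals: {unknown}")
        row_idx = np.array([pos[i] for i in individuals], dtype=int)
        ids = list(individuals)
    if loci is None:
        col_idx = np.arange(g.n_loci)
        names = list(g.locus_names)
    else:
        pos = {v: i for i, v in enumerate(g.locus_names)}
        unknown = [n for n in loci if n not in pos]
        if unknown:
            raise KeyError(f"unknown loci: {unknown}")
        col_idx = np.array([pos[n] for n in loci], dtype=int)
        names = list(loci)
    return GenotypeMatrix(
        individual_ids=ids,
        locus_names=names,
        calls=g.calls[np.ix_(row_idx, col_idx)],
        population_label=g.population_label,
    )


def concatenate(a: GenotypeMatrix, b: GenotypeMatrix, label: str = "") -> GenotypeMatrix:
    """Stack two matrices with identical locus panels row-wise."""
    if a.locus_names != b.locus_names:
        raise ValueError(
            f"locus panels differ: {a.locus_names} vs {b.locus_names}"
        )
    dup = set(a.individual_ids) & set(b.individual_ids)
    if dup:
        raise ValueError(f"duplicate individual ids across matrices: {sorted(dup)}")
    return GenotypeMatrix(
        individual_ids=a.individual_ids + b.individual_ids,
        locus_names=list(a.locus_names),
        calls=np.concatenate([a.calls, b.calls], axis=0),
        population_label=label or f"{a.population_label}+{b.population_label}",
    )


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------


def _coerce_half_calls(calls: np.ndarray, context: str) -> np.ndarray:
    half = (calls == MISSING).sum(axis=-1) == 1
    n_half = int(half.sum())
    if n_half:
        logger.warning(
            "%s: %d half-called genotype(s) (one allele missing) coerced to "
            "fully missing",
            context,
            n_half,
        )
        calls = calls.copy()
        calls[half] = MISSING
    return calls


def read_genepop_populations(path: str | Path) -> list[GenotypeMatrix]:
    """Parse a GENEPOP file into one :class:`GenotypeMatrix` per ``pop`` block.

    Accepts 2- and 3-digit allele coding (inferred from token width, which
    must be consistent across the file); ``0``/``00``/``000`` code a missing
    allele.  Duplicate individual ids — common in the wild because GENEPOP
    names populations after their last individual — are uniquified with a
    numeric suffix and logged.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeParseError("empty file", line=1)
    title = lines[0].strip()

    locus_names: list[str] = []
    i = 1
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.lower() == "pop":
            break
        if stripped:
            locus_names.extend(s.strip() for s in stripped.split(",") if s.strip())
        i += 1
    if not locus_names:
        raise GenotypeParseError("no locus names before first 'pop'", line=i + 1)
    if i >= len(lines):
        raise GenotypeParseError("no 'pop' line found", line=len(lines))
    if len(set(locus_names)) != len(locus_names):
        raise GenotypeParseError("duplicate locus names in header")

    L = len(locus_names)
    blocks: list[tuple[list[str], list[list[tuple[int, int]]]]] = []
    width: int | None = None
    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            if ids:
                blocks.append((ids, rows))
            ids, rows = [], []
            continue
        if "," not in stripped:
            raise GenotypeParseError(
                f"expected 'id , genotypes' row, got {stripped!r}", line=lineno + 1
            )
        ind_id, _, geno_part = stripped.partition(",")
        tokens = geno_part.split()
        if len(tokens) != L:
            raise GenotypeParseError(
                f"individual {ind_id.strip()!r} has {len(tokens)} genotypes, "
                f"expected {L}",
                line=lineno + 1,
            )
        row = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenotypeParseError(
                    f"bad genotype token {tok!r} (expected 4 or 6 digits)",
                    line=lineno + 1,
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenotypeParseError(
                    f"inconsistent allele-code width: token {tok!r} is "
                    f"{w}-digit but file started with {width}-digit coding",
                    line=lineno + 1,
                )
            row.append((int(tok[:w]), int(tok[w:])))
        ids.append(ind_id.strip())
        rows.append(row)
    if ids:
        blocks.append((ids, rows))
    if not blocks:
        raise GenotypeParseError("no individuals found after 'pop'")

    out = []
    for b, (ids, rows) in enumerate(blocks):
        seen: dict[str, int] = {}
        unique_ids = []
        for ind in ids:
            if ind in seen:
                seen[ind] += 1
                new = f"{ind}_{seen[ind]}"
                logger.warning(
                    "%s: duplicate individual id %r renamed to %r", path.name, ind, new
                )
                unique_ids.append(new)
            else:
                seen[ind] = 1
                unique_ids.append(ind)
        calls = np.array(rows, dtype=np.int32)
        calls = _coerce_half_calls(calls, f"{path.name} pop {b + 1}")
        label = title if len(blocks) == 1 else f"{title}:pop{b + 1}"
        out.append(
            GenotypeMatrix(
                individual_ids=unique_ids,
                locus_names=list(locus_names),
                calls=calls,
                population_label=label,
            )
        )
    return out


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Parse a single-population GENEPOP file.

    Raises if the file contains several ``pop`` blocks; use
    :func:`read_genepop_populations` for multi-population files.
    """
    pops = read_genepop_populations(path)
    if len(pops) != 1:
        raise GenotypeParseError(
            f"{Path(path).name} contains {len(pops)} populations; use "
            "read_genepop_populations()"
        )
    return pops[0]


def write_genepop(
    pops: GenotypeMatrix | Sequence[GenotypeMatrix],
    path: str | Path,
    title: str | None = None,
) -> None:
    """Write one or more populations as a 3-digit GENEPOP file."""
    if isinstance(pops, GenotypeMatrix):
        pops = [pops]
    if not pops:
        raise ValueError("nothing to write")
    locus_names = pops[0].locus_names
    for g in pops:
        if g.locus_names != locus_names:
            raise ValueError("all populations must share one locus panel")
        if (g.calls > 999).any():
            raise ValueError("allele codes must be < 1000 for 3-digit GENEPOP")
    out = [title if title is not None else (pops[0].population_label or "msatyard export")]
    out.extend(locus_names)
    for g in pops:
        out.append("pop")
        for i, ind in enumerate(g.individual_ids):
            toks = [f"{a1:03d}{a2:03d}" for a1, a2 in g.calls[i]]
            out.append(f"{ind} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_NA_TOKENS = {"", "na", "nan", "none", "0", "missing", "."}


def _parse_allele(tok: str, lineno: int | None = None) -> int:
    tok = tok.strip()
    if tok.lower() in _NA_TOKENS:
        return MISSING
    try:
        v = int(tok)
    except ValueError:
        raise GenotypeParseError(f"non-integer allele {tok!r}", line=lineno) from None
    if v < 0:
        raise GenotypeParseError(f"negative allele {tok!r}", line=lineno)
    return v


def read_genotype_table(
    path: str | Path,
    dialect: str = "auto",
    sep: str | None = None,
    population_label: str = "",
) -> GenotypeMatrix:
    """Read the tabular CSV/TSV dialect: one row per individual.

    Two layouts are supported.  ``two_column``: a pair of columns per locus
    named ``<locus>.a1`` / ``<locus>.a2``.  ``joined``: one column per locus
    holding ``"141/143"``.  ``dialect="auto"`` picks by header inspection.
    ``NA``/blank/``0`` mark missing alleles; a half-missing genotype is
    coerced to fully missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise GenotypeParseError("table needs an id column plus locus columns")
    id_col = df.columns[0]
    ids = [s.strip() for s in df[id_col]]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise GenotypeParseError(f"duplicate individual ids: {dups}")

    cols = list(df.columns[1:])
    if dialect == "auto":
        dialect = "two_column" if any(c.endswith(".a1") for c in cols) else "joined"

    if dialect == "two_column":
        loci = []
        for c in cols:
            if c.endswith(".a1"):
                base = c[:-3]
                if f"{base}.a2" not in cols:
                    raise GenotypeParseError(f"column {base}.a2 missing for {c}")
                loci.append(base)
            elif not c.endswith(".a2"):
                raise GenotypeParseError(f"unexpected column {c!r} in two_column dialect")
        calls = np.zeros((len(ids), len(loci), 2), dtype=np.int32)
        for j, locus in enumerate(loci):
            for i in range(len(ids)):
                a1 = _parse_allele(df[f"{locus}.a1"].iloc[i], i + 2)
                a2 = _parse_allele(df[f"{locus}.a2"].iloc[i], i + 2)
                calls[i, j] = (a1, a2)
    elif dialect == "joined":
        loci = cols
        calls = np.zeros((len(ids), len(loci), 2), dtype=np.int32)
        for j, locus in enumerate(loci):
            for i, cell in enumerate(df[locus]):
                cell = cell.strip()
                if cell.lower() in _NA_TOKENS:
                    continue
                if "/" not in cell:
                    raise GenotypeParseError(
                        f"expected 'a1/a2' in column {locus!r}, got {cell!r}",
                        line=i + 2,
                    )
                a1s, _, a2s = cell.partition("/")
                calls[i, j] = (_parse_allele(a1s, i + 2), _parse_allele(a2s, i + 2))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    calls = _coerce_half_calls(calls, path.name)
    return GenotypeMatrix(
        individual_ids=ids,
        locus_names=loci,
        calls=calls,
        population_label=population_label or path.stem,
    )


def write_genotype_table(
    g: GenotypeMatrix, path: str | Path, dialect: str = "joined", sep: str = ","
) -> None:
    """Write the tabular dialect (``joined`` or ``two_column``)."""
    data: dict[str, list[str]] = {"id": list(g.individual_ids)}
    typed = g.typed_mask
    if dialect == "joined":
        for j, locus in enumerate(g.locus_names):
            data[locus] = [
                f"{g.calls[i, j, 0]}/{g.calls[i, j, 1]}" if typed[i, j] else "NA"
                for i in range(g.n_individuals)
            ]
    elif dialect == "two_column":
        for j, locus in enumerate(g.locus_names):
            for k, suf in enumerate((".a1", ".a2")):
                data[locus + suf] = [
                    str(g.calls[i, j, k]) if typed[i, j] else "NA"
                    for i in range(g.n_individuals)
                ]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Reference population
# ---------------------------------------------------------------------------


@dataclass
class ReferencePopulation:
    """The yardstick: genotypes plus their full-panel diversity summary.

    ``full_panel_summary`` holds the across-locus mean A/He/Ho of the
    reference computed once over ``loci_used`` — these full-panel values are
    what calibrated indices are rescaled by.
    """

    genotypes: GenotypeMatrix
    full_panel_summary: "object"  # PopulationDiversity; typed loosely to avoid a cycle
    label: str = "reference"
    loci_used: list[str] = field(default_factory=list)


def build_reference(
    g_main: GenotypeMatrix,
    g_other: GenotypeMatrix,
    n_select: int,
    seed: int,
    label: str = "reference",
    he_estimator: str = "unbiased",
) -> ReferencePopulation:
    """Combine a random subsample of ``g_main`` with all of ``g_other``.

    Balances sampling intensity between two areas: ``n_select`` individuals
    are drawn from ``g_main`` *without* replacement (this constructs a real
    reference set, distinct from the with-replacement resampling used later
    for sample-size correction), then pooled with every individual of
    ``g_other``.  Selection is reproducible from ``seed``; the result always
    has ``n_select + len(g_other)`` individuals.
    """
    from .diversity import population_summary

    if g_main.locus_names != g_other.locus_names:
        raise ValueError(
            "locus panels differ between the two matrices: "
            f"{g_main.locus_names} vs {g_other.locus_names}"
        )
    if not (0 < n_select <= g_main.n_individuals):
        raise ValueError(
            f"n_select={n_select} not in [1, {g_main.n_individuals}]"
        )
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(g_main.n_individuals, size=n_select, replace=False))
    chosen = subset(g_main, individuals=[g_main.individual_ids[i] for i in pick])
    combined = concatenate(chosen, g_other, label=label)
    summary = population_summary(combined, he_estimator=he_estimator)
    return ReferencePopulation(
        genotypes=combined,
        full_panel_summary=summary,
        label=label,
        loci_used=list(combined.locus_names),
    )
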