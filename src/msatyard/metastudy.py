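"""Batch calibration of literature-derived diversity tables.

Published diversity values enter through a long (tidy) TSV, one row per
(study, population, locus):

    study_id  population_label  N  locus  A  He  Ho  [source]

Blank index cells mean "not reported", never 0.  A row with locus ``*``
carries population-mean indices for studies that publish no per-locus
values.  Each (study, population) becomes a
:class:`~msatyard.yardstick.PublishedPopulation`; batch comparison against
the reference yields one calibrated result per population, with per-row
seeds derived deterministically from a master seed so the whole batch is
reproducible yet rows stay independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import ReferencePopulation
from .yardstick import (
    DEFAULT_MIN_SHARED,
    PublishedPopulation,
    YardstickResult,
    yardstick_compare,
)

logger = logging.getLogger(__name__)

MEAN_ROW = "*"
_INDEX_COLS = ("A", "He", "Ho")


@dataclass
class StudyTable:
    """Literature-derived populations plus per-study panel bookkeeping."""

    populations: list[PublishedPopulation]
    panels: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.populations)


@dataclass
class ComparisonFailure:
    """A batch row that could not be calibrated (kept, never dropped)."""

    target_label: str
    study_id: str
    reason: str


def read_study_table(path: str | Path) -> StudyTable:
    """Read and validate the long-format study TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["study_id", "population_label", "N", "locus"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing columns {missing_cols}")
    dup = df.duplicated(subset=["study_id", "population_label", "locus"])
    if dup.any():
        rows = df[dup][["study_id", "population_label", "locus"]].values.tolist()
        raise ValueError(f"{path.name}: duplicate (study, population, locus) rows: {rows}")

    def parse_val(cell: str, col: str, rowno: int) -> float | None:
        cell = cell.strip()
        if cell == "" or cell.lower() in ("na", "nan"):
            return None
        try:
            v = float(cell)
        except ValueError:
            raise ValueError(f"{path.name} row {rowno}: bad {col} value {cell!r}") from None
        if col in ("He", "Ho") and not (0.0 <= v <= 1.0):
            raise ValueError(f"{path.name} row {rowno}: {col}={v} outside [0, 1]")
        if col == "A" and v < 1:
            raise ValueError(f"{path.name} row {rowno}: A={v} < 1")
        return v

    pops: list[PublishedPopulation] = []
    panels: dict[str, set[str]] = {}
    provenance: dict[tuple[str, str], str] = {}
    for (study, label), grp in df.groupby(["study_id", "population_label"], sort=False):
        ns = {s.strip() for s in grp["N"]}
        if len(ns) != 1:
            raise ValueError(f"{path.name}: inconsistent N for {study}/{label}: {ns}")
        n = int(float(ns.pop()))
        per_locus: dict[str, dict[str, float]] = {}
        mean_only: dict[str, float] | None = None
        for rowno, row in grp.iterrows():
            vals = {
                c: v
                for c in _INDEX_COLS
                if c in df.columns
                and (v := parse_val(row[c], c, rowno + 2)) is not None
            }
            locus = row["locus"].strip()
            if locus == MEAN_ROW:
                mean_only = vals
            else:
                per_locus[locus] = vals
                panels.setdefault(study, set()).add(locus)
        pops.append(
            PublishedPopulation(
                study_id=study,
                label=label,
                N=n,
                per_locus=per_locus,
                mean_only=mean_only,
            )
        )
        if "source" in df.columns:
            provenance[(study, label)] = grp["source"].iloc[0]
    return StudyTable(
        populations=pops,
        panels={k: sorted(v) for k, v in panels.items()},
        provenance=provenance,
    )


def batch_compare(
    ref: ReferencePopulation,
    table: StudyTable,
    n_rep: int = 1000,
    seed: int = 0,
    he_estimator: str = "unbiased",
    aliases: Mapping[str, str] | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> list[YardstickResult | ComparisonFailure]:
    """One calibrated comparison per table row, in table order.

    Row i uses seed ``seed + i`` so any single row can be reproduced in
    isolation.  Rows with no shared loci yield a :class:`ComparisonFailure`
    record rather than aborting the batch.
    """
    out: list[YardstickResult | ComparisonFailure] = []
    for i, pub in enumerate(table.populations):
        try:
            out.append(
                yardstick_compare(
                    ref,
                    pub,
                    n_rep=n_rep,
                    seed=seed + i,
                    he_estimator=he_estimator,
                    aliases=aliases,
                    min_shared=min_shared,
                )
            )
        except ValueError as exc:
            logger.warning("row %d (%s/%s) failed: %s", i, pub.study_id, pub.label, exc)
            out.append(
                ComparisonFailure(
                    target_label=pub.label, study_id=pub.study_id, reason=str(exc)
                )
            )
    return out


def _published_means(pub: PublishedPopulation) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for key in _INDEX_COLS:
        if pub.per_locus:
            xs = [v[key] for v in pub.per_locus.values() if key in v]
            out[key] = float(np.mean(xs)) if xs else None
        elif pub.mean_only:
            out[key] = pub.mean_only.get(key)
        else:
            out[key] = None
    return out


def comparison_report(
    results: Sequence[YardstickResult | ComparisonFailure],
    originals: StudyTable,
    sort_by: str | None = None,
) -> pd.DataFrame:
    """Side-by-side original vs calibrated values, one row per result.

    ``loc_used`` shows "panel size / shared loci used" (e.g. ``42/17``).
    Failed rows are kept with their reason in the flags column; the report
    never silently drops a result.
    """
    if not results:
        raise ValueError("no results to report")
    by_key = {(p.study_id, p.label): p for p in originals.populations}
    by_label: dict[str, PublishedPopulation] = {}
    for p in originals.populations:
        by_label.setdefault(p.label, p)
    rows = []
    for res in results:
        if isinstance(res, ComparisonFailure):
            rows.append(
                {
                    "population": res.target_label,
                    "study_id": res.study_id,
                    "flags": f"FAILED: {res.reason}",
                }
            )
            continue
        pub = by_label.get(res.target_label)
        orig = _published_means(pub) if pub else {k: None for k in _INDEX_COLS}
        panel = len(pub.per_locus) if pub and pub.per_locus else None
        row = {
            "population": res.target_label,
            "study_id": pub.study_id if pub else "",
            "N": pub.N if pub else None,
            "loc_used": f"{panel}/{res.n_shared}" if panel else f"-/{res.n_shared}",
            "mode": res.mode,
            "orig_A": orig["A"],
            "orig_He": orig["He"],
            "orig_Ho": orig["Ho"],
            "Her": res.her,
            "Art": res.art,
            "Hec": res.hec,
            "Ac": res.ac,
            "Hoc": res.hoc,
            "seed": res.seed,
            "flags": "; ".join(res.flags),
        }
        for which in ("Hec", "Ac", "Hoc"):
            ci = res.ci(which.lower())
            row[f"{which}_ci_low"] = ci[0] if ci else None
            row[f"{which}_ci_high"] = ci[1] if ci else None
        rows.append(row)
    df = pd.DataFrame(rows)
    if sort_by is not None:
        df = df.sort_values(sort_by, kind="stable").reset_index(drop=True)
    return df


def plot_calibration(
    report: pd.DataFrame, ax=None, annotate: bool = True
):
    """Scatter of calibrated Ho vs He with the Ho = He (HWE) diagonal.

    Points above the diagonal show heterozygote deficit (e.g. Wahlund
    effect or inbreeding); below, heterozygote excess.  Requires
    matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ok = report.dropna(subset=["Hec", "Hoc"])
    ax.scatter(ok["Hec"], ok["Hoc"], s=25, zorder=3)
    if annotate:
        for _, r in ok.iterrows():
            ax.annotate(r["population"], (r["Hec"], r["Hoc"]), fontsize=7,
                        xytext=(3, 3), textcoords="offset points")
    lim = [0, max(1.0, float(ok[["Hec", "Hoc"]].max().max()) * 1.05) if len(ok) else 1.0]
    ax.plot(lim, lim, "k--", lw=1, label="Ho = He (HWE)")
    ax.set_xlabel("calibrated He (Hec)")
    ax.set_ylabel("calibrated Ho (Hoc)")
    ax.legend(frameon=False)
    return ax
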