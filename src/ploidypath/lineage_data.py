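"""Lineage-level comparative dataset: schema, I/O, validation, filtering, weights.

The unit of analysis is a genus-level lineage on one archipelago: its species
counts (native and endemic), the number of distinct ploidy levels recorded
among its species there, divergence-time estimates with uncertainty, and
indicators of island monophyly (single vs. repeat colonization) and of a
ploidy change relative to the closest non-island sister lineage.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ploidypath")

#: Archipelago codes accepted in input tables, in canonical reporting order.
ARCHIPELAGOS = ("NZ", "CI", "HI", "JF", "GI")

#: Archipelagos retained for analysis (Galápagos never survives filtering).
ANALYSIS_ARCHIPELAGOS = ("NZ", "CI", "HI", "JF")

#: Exact CSV header of the lineage table.
TABLE_COLUMNS = (
    "lineage_id", "genus", "archipelago", "n_native", "n_endemic",
    "n_ploidy_levels", "monophyletic_on_island", "ploidy_change_vs_sister",
    "stem_age", "stem_age_sd", "crown_age", "crown_age_sd",
    "interval_lower", "interval_upper", "source_pool_size",
    "prop_chrom_counted", "has_dated_phylogeny", "has_chromosome_count",
)


class SchemaError(ValueError):
    """Input table does not have the documented columns."""


class ValidationError(ValueError):
    """A row violates a record invariant."""


@dataclass
class LineageRecord:
    """One genus-level lineage on one archipelago.

    Booleans ``monophyletic_on_island`` and ``ploidy_change_vs_sister`` may be
    ``None`` when unknown; ages and interval bounds may be ``None`` when
    unavailable. Ages are in millions of years (Myr).
    """

    lineage_id: str
    genus: str
    archipelago: str
    n_native: float
    n_endemic: float
    n_ploidy_levels: float
    monophyletic_on_island: bool | None
    ploidy_change_vs_sister: bool | None
    stem_age: float
    stem_age_sd: float | None = None
    crown_age: float | None = None
    crown_age_sd: float | None = None
    interval_lower: float | None = None
    interval_upper: float | None = None
    source_pool_size: float = 0
    prop_chrom_counted: float = 0.0
    has_dated_phylogeny: bool = True
    has_chromosome_count: bool = True

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        rid = self.lineage_id
        if self.archipelago not in ARCHIPELAGOS:
            raise ValidationError(
                f"{rid}: unknown archipelago {self.archipelago!r} "
                f"(expected one of {ARCHIPELAGOS})")
        if self.n_native < 0 or self.n_endemic < 0:
            raise ValidationError(f"{rid}: negative species count")
        if self.n_endemic > self.n_native:
            raise ValidationError(
                f"{rid}: n_endemic ({self.n_endemic}) exceeds "
                f"n_native ({self.n_native})")
        if self.has_chromosome_count and self.n_ploidy_levels < 1:
            raise ValidationError(
                f"{rid}: n_ploidy_levels must be >= 1 when a chromosome "
                f"count exists")
        if not self.stem_age > 0:
            raise ValidationError(f"{rid}: stem_age must be positive")
        if self.stem_age_sd is not None and self.stem_age_sd < 0:
            raise ValidationError(f"{rid}: negative stem_age_sd")
        if not 0.0 <= self.prop_chrom_counted <= 1.0:
            raise ValidationError(f"{rid}: prop_chrom_counted outside [0, 1]")
        if self.interval_lower is not None and self.interval_upper is not None:
            for name, mean in (("stem_age", self.stem_age),
                               ("crown_age", self.crown_age)):
                if mean is None:
                    continue
                # The interval describes whichever age it was reported for;
                # require consistency only when the mean lies near the interval.
                if self.interval_lower <= mean <= self.interval_upper:
                    break
            else:
                raise ValidationError(
                    f"{rid}: neither stem nor crown mean age lies inside "
                    f"[{self.interval_lower}, {self.interval_upper}]")


@dataclass
class AnalysisDataset:
    """Records retained by the inclusion criteria, in canonical order.

    The record order is the canonical ordering inherited by every design
    matrix and covariance matrix downstream: archipelago (NZ, CI, HI, JF)
    then lineage_id lexicographic.
    """

    records: list[LineageRecord]
    weights_species: np.ndarray | None = None
    weights_ploidy: np.ndarray | None = None
    exclusion_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lineage_ids(self) -> list[str]:
        return [r.lineage_id for r in self.records]

    @property
    def archipelago_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.archipelago] = counts.get(r.archipelago, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame in canonical order (one row per lineage)."""
        return pd.DataFrame([vars(r) for r in self.records])


# ---------------------------------------------------------------------------
# Reading and writing the lineage table
# ---------------------------------------------------------------------------

_BOOL_VALUES = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(raw: str, row: int, col: str) -> bool | None:
    s = raw.strip().lower()
    if s in ("", "na", "nan", "none"):
        return None
    if s in _BOOL_VALUES:
        return _BOOL_VALUES[s]
    raise ValidationError(f"row {row}: cannot parse boolean {col}={raw!r}")


def _parse_float(raw: str, row: int, col: str) -> float | None:
    s = raw.strip()
    if s.lower() in ("", "na", "nan", "none"):
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValidationError(f"row {row}: cannot parse {col}={raw!r}") from exc


def read_lineage_table(path: str | Path) -> list[LineageRecord]:
    """Read and validate a lineage CSV/TSV table.

    The header must contain exactly the documented columns (order is not
    enforced). Unknown booleans are encoded as empty strings or ``NA``.
    Rows failing validation are reported with their 1-based data row number.
    """
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = set(TABLE_COLUMNS) - set(header)
        if missing:
            raise SchemaError(
                f"{path}: missing mandatory columns {sorted(missing)}")
        records = []
        for i, row in enumerate(reader, start=1):
            rec = LineageRecord(
                lineage_id=row["lineage_id"].strip(),
                genus=row["genus"].strip(),
                archipelago=row["archipelago"].strip(),
                n_native=_parse_float(row["n_native"], i, "n_native") or 0,
                n_endemic=_parse_float(row["n_endemic"], i, "n_endemic") or 0,
                n_ploidy_levels=_parse_float(
                    row["n_ploidy_levels"], i, "n_ploidy_levels") or 0,
                monophyletic_on_island=_parse_bool(
                    row["monophyletic_on_island"], i, "monophyletic_on_island"),
                ploidy_change_vs_sister=_parse_bool(
                    row["ploidy_change_vs_sister"], i,
                    "ploidy_change_vs_sister"),
                stem_age=_parse_float(row["stem_age"], i, "stem_age") or 0.0,
                stem_age_sd=_parse_float(row["stem_age_sd"], i, "stem_age_sd"),
                crown_age=_parse_float(row["crown_age"], i, "crown_age"),
                crown_age_sd=_parse_float(
                    row["crown_age_sd"], i, "crown_age_sd"),
                interval_lower=_parse_float(
                    row["interval_lower"], i, "interval_lower"),
                interval_upper=_parse_float(
                    row["interval_upper"], i, "interval_upper"),
                source_pool_size=_parse_float(
                    row["source_pool_size"], i, "source_pool_size") or 0,
                prop_chrom_counted=_parse_float(
                    row["prop_chrom_counted"], i, "prop_chrom_counted") or 0.0,
                has_dated_phylogeny=_parse_bool(
                    row["has_dated_phylogeny"], i, "has_dated_phylogeny")
                or False,
                has_chromosome_count=_parse_bool(
                    row["has_chromosome_count"], i, "has_chromosome_count")
                or False,
            )
            try:
                rec.validate()
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from exc
            records.append(rec)
    return records


def _format_value(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return str(v)


def write_lineage_table(records: Iterable[LineageRecord],
                        path: str | Path) -> None:
    """Write records back to CSV with the canonical header."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TABLE_COLUMNS)
        for rec in records:
            writer.writerow([_format_value(getattr(rec, c))
                             for c in TABLE_COLUMNS])


# ---------------------------------------------------------------------------
# Divergence-time uncertainty
# ---------------------------------------------------------------------------

def estimate_age_sd(mean_age: float, lower: float, upper: float,
                    z: float = 1.96) -> float:
    """SD of a divergence-time estimate from a 95% HPD/CI interval.

    Assumes normality of the longer of the interval's two tails:
    ``max(upper - mean, mean - lower) / z``. Used only when no SD was
    reported directly.
    """
    if not lower <= mean_age <= upper:
        raise ValueError(
            f"mean age {mean_age} outside interval [{lower}, {upper}]")
    if z <= 0:
        raise ValueError("z must be positive")
    return max(upper - mean_age, mean_age - lower) / z


# ---------------------------------------------------------------------------
# Inclusion criteria and weights
# ---------------------------------------------------------------------------

def _canonical_sort_key(rec: LineageRecord) -> tuple[int, str]:
    try:
        a = ANALYSIS_ARCHIPELAGOS.index(rec.archipelago)
    except ValueError:
        a = len(ANALYSIS_ARCHIPELAGOS)
    return (a, rec.lineage_id)


def filter_lineages(records: Sequence[LineageRecord],
                    compute_weights_now: bool = True) -> AnalysisDataset:
    """Apply the three inclusion criteria and build the analysis dataset.

    A lineage is retained iff it has (1) at least two native species on the
    archipelago, (2) a dated phylogeny including at least one native island
    species, and (3) at least one chromosome count from a native island
    specimen. Galápagos lineages are expected to be eliminated by these
    criteria. Returns records in canonical order with an exclusion report.
    """
    kept: list[LineageRecord] = []
    excl = {"n_native_lt_2": 0, "no_dated_phylogeny": 0,
            "no_chromosome_count": 0}
    for rec in records:
        fails = []
        if rec.n_native < 2:
            fails.append("n_native_lt_2")
        if not rec.has_dated_phylogeny:
            fails.append("no_dated_phylogeny")
        if not rec.has_chromosome_count:
            fails.append("no_chromosome_count")
        if fails:
            for f in fails:
                excl[f] += 1
        else:
            kept.append(rec)
    kept.sort(key=_canonical_sort_key)

    # Binary predictors admit no missing level: unknown flags default to False.
    cleaned = []
    for rec in kept:
        changes = {}
        if rec.monophyletic_on_island is None:
            changes["monophyletic_on_island"] = False
        if rec.ploidy_change_vs_sister is None:
            changes["ploidy_change_vs_sister"] = False
        if changes:
            logger.warning("%s: unknown %s set to false", rec.lineage_id,
                           "/".join(changes))
            rec = replace(rec, **changes)
        cleaned.append(rec)

    ds = AnalysisDataset(records=cleaned)
    ds.exclusion_report = {
        "n_input": len(records),
        "n_retained": len(cleaned),
        "excluded_by_criterion": excl,
        "retained_per_archipelago": ds.archipelago_counts,
    }
    if compute_weights_now and cleaned:
        ds.weights_species, ds.weights_ploidy = compute_weights(ds)
    return ds


def compute_weights(dataset: AnalysisDataset) -> tuple[np.ndarray, np.ndarray]:
    """Observation weights for the two responses.

    Species counts are weighted by the inverse square root of the stem-age
    SD (more certain divergence times weigh more); ploidy-level counts by
    the proportion of the lineage's endemic species with chromosome counts.

    Records without a reported SD fall back to the tail rule of
    :func:`estimate_age_sd` when interval bounds exist. A zero or missing SD
    is floored at the smallest positive SD in the dataset, which avoids an
    infinite weight while preserving the ordering of certainties.
    """
    sds = []
    for rec in dataset.records:
        sd = rec.stem_age_sd
        if sd is None and rec.interval_lower is not None \
                and rec.interval_upper is not None \
                and rec.interval_lower <= rec.stem_age <= rec.interval_upper:
            sd = estimate_age_sd(rec.stem_age, rec.interval_lower,
                                 rec.interval_upper)
        if sd is not None and sd < 0:
            raise ValidationError(f"{rec.lineage_id}: negative stem_age_sd")
        sds.append(sd)
    positive = [s for s in sds if s is not None and s > 0]
    if not positive:
        raise ValidationError(
            "no positive stem-age SD in dataset; cannot form weights")
    floor = min(positive)
    out_sds = []
    for rec, sd in zip(dataset.records, sds):
        if sd is None or sd <= 0:
            logger.warning("%s: stem_age_sd missing or zero; floored at %g",
                           rec.lineage_id, floor)
            sd = floor
        out_sds.append(sd)
    weights_species = 1.0 / np.sqrt(np.asarray(out_sds, dtype=float))

    props = []
    for rec in dataset.records:
        p = rec.prop_chrom_counted
        # "At least one counted specimen" only constrains integer species
        # counts; continuous (model-scale) counts carry no such floor.
        if float(rec.n_endemic).is_integer():
            lo = 1.0 / max(rec.n_endemic, 1.0)
        else:
            lo = 0.0
        if p < lo:
            # Criterion 3 guarantees at least one counted specimen.
            logger.warning("%s: prop_chrom_counted %.3g raised to 1/n_endemic "
                           "= %.3g", rec.lineage_id, p, lo)
            p = lo
        props.append(min(p, 1.0))
    weights_ploidy = np.asarray(props, dtype=float)

    if not (np.all(np.isfinite(weights_species))
            and np.all(weights_species > 0)):
        raise ValidationError("non-finite or non-positive species weights")
    return weights_species, weights_ploidy


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(dataset: AnalysisDataset) -> pd.DataFrame:
    """Per-archipelago and overall summary of the analysis variables.

    Rows mirror the study's summary table: lineage counts, monophyly and
    ploidy-change counts, mean (SD) endemic species, stem age, ploidy levels
    and chromosome-count completeness, and median source-pool size. SDs are
    population-style only for n=1 (reported as 0); otherwise sample SD.
    """
    if not dataset.records:
        raise ValueError("cannot summarize an empty dataset")
    df = dataset.to_frame()
    groups = [(a, df[df.archipelago == a])
              for a in ANALYSIS_ARCHIPELAGOS if (df.archipelago == a).any()]
    groups.append(("All", df))

    def mean_sd(s: pd.Series) -> tuple[float, float]:
        m = float(s.mean())
        sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
        return m, sd

    rows = {}
    for name, g in groups:
        e_m, e_s = mean_sd(g.n_endemic)
        a_m, a_s = mean_sd(g.stem_age)
        p_m, p_s = mean_sd(g.n_ploidy_levels)
        c_m, c_s = mean_sd(100.0 * g.prop_chrom_counted)
        rows[name] = {
            "n_lineages": int(len(g)),
            "n_monophyletic": int(g.monophyletic_on_island.sum()),
            "n_ploidy_change": int(g.ploidy_change_vs_sister.sum()),
            "mean_endemic": e_m, "sd_endemic": e_s,
            "mean_stem_age": a_m, "sd_stem_age": a_s,
            "mean_ploidy_levels": p_m, "sd_ploidy_levels": p_s,
            "mean_pct_chrom_counted": c_m, "sd_pct_chrom_counted": c_s,
            "median_source_pool": float(g.source_pool_size.median()),
        }
    return pd.DataFrame(rows).T


def age_correlation(records: Sequence[LineageRecord]) -> tuple[float, int]:
    """Pearson correlation between mean stem and crown ages.

    Computed over records with both ages present; returns ``(r, df)`` with
    ``df = n_pairs - 2``.
    """
    pairs = [(r.stem_age, r.crown_age) for r in records
             if r.crown_age is not None and r.stem_age is not None]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 complete stem/crown pairs, "
                         f"got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    r = float(np.corrcoef(x, y)[0, 1])
    return r, len(pairs) - 2
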