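"""Plant-like transcript (PLT) screening from similarity-search output.

Consumes standard 12-column tabular similarity-search results (the BLAST
``outfmt 6`` layout: qseqid sseqid pident length mismatch gapopen qstart
qend sstart send evalue bitscore), maps subjects to taxon groups, and
classifies each query into the three identity categories used for candidate
horizontally-transferred transcripts:

* **i** — near-identical to plant (> 95%) while still strongly matching
  insect (>= 85%): a highly conserved protein, weak HGT evidence on its own;
* **ii** — high plant identity (> 90%) but low insect identity (< 85%):
  the interesting intermediate class;
* **iii** — matches plants only, no insect hit at all: the strongest
  candidates.

Also provides the 2x2 Fisher's exact enrichment test and the 2^-ddCt
relative-expression summary used downstream of the screen.  The identity
thresholds describe observed boundaries rather than crisp rules, so all four
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

DEFAULT_EVALUE_CUTOFF = 1e-3

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

PLANT, INSECT, OTHER = "plant", "insect", "other"
CATEGORY_I, CATEGORY_II, CATEGORY_III, NOT_PLT = "i", "ii", "iii", "not_plt"


class ScreenError(ValueError):
    pass


@dataclass
class HitRecord:
    """One retained similarity-search hit."""

    query: str
    subject: str
    identity: float
    length: int
    e_value: float
    bit_score: float
    group: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ScreenError(
                f"percent identity {self.identity} outside [0, 100] "
                f"for {self.query}/{self.subject}"
            )
        if self.e_value < 0:
            raise ScreenError(f"negative E-value for {self.query}/{self.subject}")


@dataclass
class HitTable:
    """Parsed hits plus parse-time accounting."""

    records: list[HitRecord]
    n_dropped_evalue: int = 0
    n_unknown_subject: int = 0

    def by_query(self) -> dict[str, list[HitRecord]]:
        out: dict[str, list[HitRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.query, []).append(rec)
        return out


def _resolve_group(subject: str, taxon_map: dict[str, str]) -> str | None:
    """Longest-prefix match of the subject id against the mapping table."""
    best = None
    for prefix, group in taxon_map.items():
        if subject.startswith(prefix):
            if best is None or len(prefix) > len(best[0]):
                best = (prefix, group)
    return best[1] if best else None


def read_taxon_map(src: Union[str, Path, IO[str]]) -> dict[str, str]:
    """2-column TSV: subject-id-prefix, group (plant/insect/other)."""
    df = pd.read_csv(src, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ScreenError(f"taxon map must have 2 columns, got {df.shape[1]}")
    return dict(zip(df[0], df[1].str.lower()))


def parse_hits(
    src: Union[str, Path, IO[str]],
    taxon_map: dict[str, str],
    e_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> HitTable:
    """Parse 12-column tabular hits, dropping rows above the E-value cutoff.

    Subjects with no prefix in ``taxon_map`` fall into group "other"; their
    count is reported on the returned table.
    """
    try:
        df = pd.read_csv(
            src, sep="\t", header=None, names=HIT_COLUMNS, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except pd.errors.EmptyDataError:
        return HitTable([])
    except (pd.errors.ParserError, ValueError) as exc:
        raise ScreenError(f"malformed hit table: {exc}") from exc
    for col in ("pident", "evalue", "bitscore", "length"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ScreenError(f"malformed value in column {col!r} at line {line}")
        df[col] = vals
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 1
        raise ScreenError(f"missing field at line {line}")

    keep = df["evalue"] <= e_cutoff
    n_dropped = int((~keep).sum())
    records: list[HitRecord] = []
    n_unknown = 0
    for row in df[keep].itertuples(index=False):
        group = _resolve_group(row.sseqid, taxon_map)
        if group is None:
            group = OTHER
            n_unknown += 1
        records.append(
            HitRecord(
                query=row.qseqid,
                subject=row.sseqid,
                identity=float(row.pident),
                length=int(row.length),
                e_value=float(row.evalue),
                bit_score=float(row.bitscore),
                group=group,
            )
        )
    return HitTable(records, n_dropped_evalue=n_dropped, n_unknown_subject=n_unknown)


@dataclass
class CategoryThresholds:
    """Identity boundaries of the three-category classifier (percent)."""

    plant_high: float = 95.0   # category i requires plant identity above this
    insect_high: float = 85.0  # category i requires insect identity at/above this
    plant_mid: float = 90.0    # category ii requires plant identity above this
    insect_low: float = 85.0   # category ii requires insect identity below this


@dataclass
class PLTCall:
    query: str
    best_plant: float | None
    best_insect: float | None
    category: str


def categorize(
    query: str,
    hits: Iterable[HitRecord],
    thresholds: CategoryThresholds | None = None,
) -> PLTCall:
    """Classify one query from its retained hits.

    A query with no plant hit, or whose best insect identity is at least the
    best plant identity (ties conservative), is not a PLT.
    """
    th = thresholds or CategoryThresholds()
    plant = [h.identity for h in hits if h.group == PLANT]
    insect = [h.identity for h in hits if h.group == INSECT]
    best_plant = max(plant) if plant else None
    best_insect = max(insect) if insect else None

    if best_plant is None:
        cat = NOT_PLT
    elif best_insect is None:
        cat = CATEGORY_III
    elif best_insect >= best_plant:
        cat = NOT_PLT
    elif best_plant > th.plant_high and best_insect >= th.insect_high:
        cat = CATEGORY_I
    elif best_plant > th.plant_mid and best_insect < th.insect_low:
        cat = CATEGORY_II
    else:
        cat = NOT_PLT
    return PLTCall(query, best_plant, best_insect, cat)


def categorize_all(
    table: HitTable, thresholds: CategoryThresholds | None = None
) -> list[PLTCall]:
    return [
        categorize(q, hits, thresholds) for q, hits in sorted(table.by_query().items())
    ]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding the observed table's (with 1e-12 absolute
    slack for floating-point ties); computed in log space.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ScreenError("Fisher table counts must be non-negative")
    if sum(counts) == 0:
        raise ScreenError("Fisher table is all zero")
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(support, n, r1, c1)
    p_obs = np.exp(hypergeom.logpmf(a, n, r1, c1))
    p = float(np.exp(logp)[np.exp(logp) <= p_obs + 1e-12].sum())
    return min(p, 1.0)


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """BH-adjusted q-values (optional; the screen applies no correction by
    default)."""
    p = np.asarray(list(p_values), dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def fold_change_ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calib: float,
    ct_ref_calib: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,calib - Ct_ref,calib);
    the reference gene (e.g. actin) normalizes each sample, the calibrator
    sample anchors the scale.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_calib, ct_ref_calib):
        if not np.isfinite(v):
            raise ScreenError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_calib - ct_ref_calib)
    return float(2.0 ** (-ddct))
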