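"""Lineage-restriction screen for candidate ectoplasmic-network/bothrosome
proteins.

The ectoplasmic network and its bothrosome are unique to Labyrinthulomycota,
so proteins that (a) rise in abundance once zoospores settle and start
building the network and (b) have identifiable homologs only within
Labyrinthulomycota (proxied by *Hondaea fermentalgiana*) are candidate
components.  Two routes flag a protein:

* the hit-classification route: retain the top-N homology hits per query,
  classify each query as ``aurli_only`` (no stramenopile hits), ``laby_only``
  (hits only to Hondaea), ``stramenopile_not_hondaea`` (>= N hits to other
  stramenopiles, all scoring above the best Hondaea hit, or no Hondaea hit
  at all), or ``both``; for ``both`` queries the best-Hondaea minus
  best-other score deltas are binned by empirical percentile
  (0-85, 85-90, 90-95, 95-97.5, 97.5-100), larger delta = more Hondaea-like;
* the orthogroup route: the query's orthogroup spans >= 2 Labyrinthulomycota
  genomes, <= 1 non-Labyrinthulomycota genome, has >= 1 Hondaea copy, and
  the protein is upregulated at one of the post-settlement timepoints.

Candidates are the union of the two routes, restricted to proteins
upregulated at the configured timepoints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .de import DESummary
from .io import OrthogroupTable

GROUPS = ("aurli_only", "laby_only", "stramenopile_not_hondaea", "both")
BINS = ("Q0_85", "Q85_90", "Q90_95", "Q95_975", "Q975_100")
_BIN_EDGES = (85.0, 90.0, 95.0, 97.5)  # upper percentile edge of each bin but the last
LABY_CLASS = "laby_hondaea"
OTHER_CLASS = "other_stramenopile"


@dataclass
class ScreenConfig:
    """Knobs of the lineage screen (defaults follow the published procedure)."""

    top_n: int = 5
    min_laby_genomes: int = 2
    max_nonlaby_genomes: int = 1
    required_hondaea_copies: int = 1
    hondaea_genome: str = "Honfer"
    upregulated_timepoints: tuple[str, ...] = ("T4", "T6", "T8")
    blast_qualifying_bins: tuple[str, ...] = ("Q975_100",)
    include_aurli_only: bool = False
    conservation_min_genomes: int = 3  # annotation flag: orthogroup in >= 3 of the laby genomes

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        unknown = set(self.blast_qualifying_bins) - set(BINS)
        if unknown:
            raise ValidationError(f"unknown quantile bins: {sorted(unknown)}")


@dataclass
class LineageCall:
    query: str
    group: str
    delta_bitscore: float | None = None
    delta_log10_evalue: float | None = None  # -log10 scale; larger = Hondaea hit stronger
    delta_pident: float | None = None
    quantile_bin: str | None = None


@dataclass
class CandidateRecord:
    protein_id: str
    passed_blast: bool
    passed_orthogroup: bool
    group: str | None = None
    quantile_bin: str | None = None
    condition_flags: dict[str, bool] = field(default_factory=dict)
    upregulated_at: set[str] = field(default_factory=set)

    @property
    def combined(self) -> bool:
        return self.passed_blast or self.passed_orthogroup


# ---------------------------------------------------------------------------
# hit selection and classification


def select_top_hits(hits: pd.DataFrame, top_n: int = 5) -> pd.DataFrame:
    """Retain at most ``top_n`` hits per query, best first.

    Ranking: lowest e-value, then highest percent identity, then highest
    bitscore, then lexicographically smallest subject id.
    """
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        by=["query", "evalue", "pident", "bitscore", "subject"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    return ordered.groupby("query", sort=False).head(top_n).reset_index(drop=True)


def _best_by_bitscore(rows: pd.DataFrame) -> pd.Series:
    # maximum bitscore; ties broken by lowest e-value
    ordered = rows.sort_values(by=["bitscore", "evalue"], ascending=[False, True],
                               kind="mergesort")
    return ordered.iloc[0]


def classify_lineage(top_hits: pd.DataFrame, queries: list[str],
                     top_n: int = 5) -> list[LineageCall]:
    """Assign each query in ``queries`` exactly one lineage group.

    ``top_hits`` must already be reduced by :func:`select_top_hits` (with the
    same ``top_n``) and carry a ``taxon_class`` column with values
    ``laby_hondaea`` / ``other_stramenopile``.
    """
    if not top_hits.empty:
        bad = set(top_hits["taxon_class"].unique()) - {LABY_CLASS, OTHER_CLASS}
        if bad:
            raise ValidationError(f"unknown taxon_class values: {sorted(bad)}")
    by_query = dict(tuple(top_hits.groupby("query"))) if not top_hits.empty else {}
    calls = []
    for q in queries:
        rows = by_query.get(q)
        if rows is None or rows.empty:
            calls.append(LineageCall(q, "aurli_only"))
            continue
        laby = rows[rows["taxon_class"] == LABY_CLASS]
        other = rows[rows["taxon_class"] == OTHER_CLASS]
        if other.empty:
            calls.append(LineageCall(q, "laby_only"))
            continue
        if laby.empty:
            calls.append(LineageCall(q, "stramenopile_not_hondaea"))
            continue
        best_laby = _best_by_bitscore(laby)
        n_better = int((other["bitscore"] > best_laby["bitscore"]).sum())
        if n_better >= top_n:
            calls.append(LineageCall(q, "stramenopile_not_hondaea"))
            continue
        best_other = _best_by_bitscore(other)
        calls.append(LineageCall(
            q, "both",
            delta_bitscore=float(best_laby["bitscore"] - best_other["bitscore"]),
            delta_log10_evalue=float(
                -math.log10(max(best_laby["evalue"], 1e-300))
                + math.log10(max(best_other["evalue"], 1e-300))
            ),
            delta_pident=float(best_laby["pident"] - best_other["pident"]),
        ))
    return calls


def bin_deltas(calls: list[LineageCall]) -> list[LineageCall]:
    """Bin the ``both``-group bitscore deltas by empirical percentile.

    Percentiles use the maximum tie rank (share of deltas <= the value), so
    a query at the maximum delta — including the degenerate single-delta
    case — lands in Q975_100.
    """
    both = [c for c in calls if c.group == "both"]
    if not both:
        warnings.warn("no 'both'-group calls; nothing to bin")
        return calls
    deltas = np.array([c.delta_bitscore for c in both])
    if np.all(deltas == deltas[0]) and len(deltas) > 1:
        warnings.warn("all bitscore deltas identical; percentile bins are degenerate")
    order = np.argsort(deltas, kind="mergesort")
    # max tie rank: number of deltas <= this delta
    pct = np.array([np.searchsorted(deltas[order], d, side="right") for d in deltas])
    pct = 100.0 * pct / len(deltas)
    for c, p in zip(both, pct):
        idx = int(np.searchsorted(_BIN_EDGES, p, side="left"))
        c.quantile_bin = BINS[idx]
    return calls


# ---------------------------------------------------------------------------
# orthogroup filter


def orthogroup_filter(og: OrthogroupTable, de_summary: DESummary, cfg: ScreenConfig,
                      proteins: list[str], genome: str = "Aurli") -> dict[str, dict[str, bool]]:
    """Evaluate the four orthogroup-screen conditions for each protein.

    Returns protein -> flags ``cond1``.. ``cond4`` plus ``passed`` and the
    annotation-only ``conserved`` flag (orthogroup present in >=
    ``conservation_min_genomes`` of the Labyrinthulomycota genomes).
    """
    og_of = og.orthogroup_of(genome) if len(og.counts) else {}
    laby = og.laby_genomes
    nonlaby = og.nonlaby_genomes
    out: dict[str, dict[str, bool]] = {}
    for pid in proteins:
        name = og_of.get(pid)
        upregulated = bool(de_summary.upregulated_at(pid)
                           & set(cfg.upregulated_timepoints))
        if name is None:
            flags = {"cond1_min_laby": False, "cond2_max_nonlaby": False,
                     "cond3_upregulated": upregulated, "cond4_hondaea_copy": False,
                     "conserved": False}
        else:
            counts = og.counts.loc[name]
            n_laby = int((counts[laby] > 0).sum()) if laby else 0
            n_nonlaby = int((counts[nonlaby] > 0).sum()) if nonlaby else 0
            hondaea = int(counts.get(cfg.hondaea_genome, 0))
            flags = {
                "cond1_min_laby": n_laby >= cfg.min_laby_genomes,
                "cond2_max_nonlaby": n_nonlaby <= cfg.max_nonlaby_genomes,
                "cond3_upregulated": upregulated,
                "cond4_hondaea_copy": hondaea >= cfg.required_hondaea_copies,
                "conserved": n_laby >= cfg.conservation_min_genomes,
            }
        flags["passed"] = (flags["cond1_min_laby"] and flags["cond2_max_nonlaby"]
                           and flags["cond3_upregulated"] and flags["cond4_hondaea_copy"])
        out[pid] = flags
    return out


# ---------------------------------------------------------------------------
# combination


def combine_candidates(blast_calls: list[LineageCall],
                       og_flags: dict[str, dict[str, bool]],
                       de_summary: DESummary,
                       cfg: ScreenConfig) -> list[CandidateRecord]:
    """Union of the two screening routes, restricted to upregulated proteins."""
    call_of = {c.query: c for c in blast_calls}
    bin_rank = {b: i for i, b in enumerate(BINS)}
    floor = min(bin_rank[b] for b in cfg.blast_qualifying_bins)
    records = []
    proteins = sorted(set(call_of) | set(og_flags))
    for pid in proteins:
        up_at = de_summary.upregulated_at(pid) & set(cfg.upregulated_timepoints)
        call = call_of.get(pid)
        blast_ok = False
        if call is not None:
            if call.group == "laby_only":
                blast_ok = True
            elif call.group == "both" and call.quantile_bin is not None:
                blast_ok = bin_rank[call.quantile_bin] >= floor
            elif call.group == "aurli_only" and cfg.include_aurli_only:
                blast_ok = True
        flags = og_flags.get(pid, {})
        og_ok = bool(flags.get("passed", False))
        if not up_at:
            blast_ok = og_ok = False
        rec = CandidateRecord(
            protein_id=pid,
            passed_blast=blast_ok,
            passed_orthogroup=og_ok,
            group=call.group if call else None,
            quantile_bin=call.quantile_bin if call else None,
            condition_flags=dict(flags),
            upregulated_at=up_at,
        )
        if rec.combined:
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# cross-study directional concordance


def concordance_crosstab(protein_calls: dict[str, str],
                         transcript_calls: dict[str, str]) -> pd.DataFrame:
    """Direction-by-direction cross-tabulation over genes significant in both
    a protein-level and a transcript-level study.

    Inputs map gene -> direction ('up' | 'down').  Returns a 2x2 count table
    (protein direction in rows, transcript direction in columns); the
    diagonal is the concordant mass.
    """
    for name, calls in (("protein", protein_calls), ("transcript", transcript_calls)):
        bad = {g: d for g, d in calls.items() if d not in ("up", "down")}
        if bad:
            raise ValidationError(f"{name} calls must be 'up' or 'down': {bad}")
    shared = sorted(set(protein_calls) & set(transcript_calls))
    table = pd.DataFrame(0, index=["up", "down"], columns=["up", "down"])
    for g in shared:
        table.loc[protein_calls[g], transcript_calls[g]] += 1
    table.index.name = "protein"
    table.columns.name = "transcript"
    return table
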