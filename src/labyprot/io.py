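"""Readers, writers and validated in-memory containers for every table the
pipeline touches.

All external formats are plain TSV (lines starting with ``#`` are comments):

* intensity table — proteins in rows, one column per sample, header row of
  sample ids; the first column holds protein ids;
* sample design — columns ``sample_id``, ``timepoint``, ``replicate`` and
  optionally ``batch`` (defaults to the replicate);
* homology hits — the 12-column "outfmt 6" dialect (qseqid, sseqid, pident,
  length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore);
* orthogroups — one row per orthogroup, one column per genome, cells are
  comma-separated member ids (``Orthogroups.tsv`` dialect);
* annotation maps — two columns, ``protein_id`` then ``term``.

Raw reporter intensities of 0 (or empty cells) are treated as missing by
default, following the MaxQuant convention of writing 0 for unquantified
reporter channels; the sentinel is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

LABY = "labyrinthulomycota"
OTHER = "other"


# ---------------------------------------------------------------------------
# sample design


@dataclass
class SampleDesign:
    """Per-sample metadata: timepoint (hours), replicate and batch labels.

    ``frame`` is indexed by ``sample_id`` with columns ``timepoint`` (int),
    ``replicate`` (str) and ``batch`` (str).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = {"timepoint", "replicate", "batch"}
        missing = required - set(f.columns)
        if missing:
            raise ValidationError(f"design lacks columns: {sorted(missing)}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in design: {dups}")
        pairs = f[["timepoint", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            bad = pairs[pairs.duplicated()].tolist()
            raise ValidationError(f"duplicate (timepoint, replicate) pairs: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def timepoints(self) -> list[int]:
        """Ordered distinct timepoints (hours)."""
        return sorted(self.frame["timepoint"].unique().tolist())

    def samples_at(self, timepoint: int) -> list[str]:
        return list(self.frame.index[self.frame["timepoint"] == timepoint])

    def replicates_per_timepoint(self) -> dict[int, int]:
        return self.frame.groupby("timepoint").size().to_dict()

    def require_replication(self, min_replicates: int = 2) -> None:
        """Raise unless every timepoint carries at least ``min_replicates`` samples."""
        under = {t: n for t, n in self.replicates_per_timepoint().items() if n < min_replicates}
        if under:
            raise ValidationError(
                f"timepoints with fewer than {min_replicates} replicates: {under}"
            )

    def subset(self, sample_ids: list[str]) -> "SampleDesign":
        return SampleDesign(self.frame.loc[sample_ids].copy())


@dataclass
class IntensityMatrix:
    """Protein-by-sample abundance grid plus its design.

    ``values`` is a DataFrame (rows = protein ids, columns = sample ids);
    missing measurements are NaN.  ``scale_tag`` records the processing
    stage: ``raw`` (positive intensity units), ``glog`` (generalized-log2),
    or ``batch_corrected``.
    """

    values: pd.DataFrame
    design: SampleDesign
    scale_tag: str = "raw"

    _SCALES = ("raw", "glog", "batch_corrected")

    def __post_init__(self) -> None:
        if self.scale_tag not in self._SCALES:
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate protein id: {dup!r}")
        extra = [s for s in self.values.columns if s not in self.design.frame.index]
        if extra:
            raise ValidationError(f"samples absent from design: {extra}")
        # align design order to the data columns
        self.values = self.values.astype(float)
        if self.scale_tag == "raw":
            present = self.values.to_numpy()
            if np.any(present[np.isfinite(present)] <= 0):
                raise ValidationError("raw intensities must be > 0 where present")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def complete_rows(self) -> "IntensityMatrix":
        """Submatrix of proteins quantified in every sample."""
        keep = self.values.notna().all(axis=1)
        return IntensityMatrix(self.values.loc[keep].copy(), self.design, self.scale_tag)

    def with_values(self, values: pd.DataFrame, scale_tag: str) -> "IntensityMatrix":
        return IntensityMatrix(values, self.design, scale_tag)


@dataclass
class AnnotationMap:
    """Term -> protein-id sets within one namespace (KOG class, ko group, GO term, ...)."""

    namespace: str
    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    NAMESPACES = ("KOG_class", "ko_group", "GO_term", "pfam", "custom")

    def __post_init__(self) -> None:
        if self.namespace not in self.NAMESPACES:
            raise ValidationError(f"unknown annotation namespace {self.namespace!r}")
        for term, members in self.terms.items():
            if not members:
                raise ValidationError(f"annotation term {term!r} has no members")
            if not all(isinstance(p, str) for p in members):
                raise ValidationError(f"non-string protein id under term {term!r}")

    def annotated_proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.terms.values():
            out |= members
        return out


@dataclass
class OrthogroupTable:
    """Orthogroup membership across genomes.

    ``counts``: DataFrame orthogroup x genome of member copy counts.
    ``members``: orthogroup -> genome -> tuple of member ids.
    ``lineages``: genome -> 'labyrinthulomycota' | 'other'.
    """

    counts: pd.DataFrame
    members: dict[str, dict[str, tuple[str, ...]]]
    lineages: dict[str, str]

    def __post_init__(self) -> None:
        unlabeled = [g for g in self.counts.columns if g not in self.lineages]
        if unlabeled:
            raise ValidationError(f"genomes without lineage label: {unlabeled}")
        bad = {g: v for g, v in self.lineages.items() if v not in (LABY, OTHER)}
        if bad:
            raise ValidationError(f"lineage labels must be '{LABY}' or '{OTHER}': {bad}")

    @property
    def laby_genomes(self) -> list[str]:
        return [g for g in self.counts.columns if self.lineages[g] == LABY]

    @property
    def nonlaby_genomes(self) -> list[str]:
        return [g for g in self.counts.columns if self.lineages[g] == OTHER]

    def orthogroup_of(self, genome: str) -> dict[str, str]:
        """Member protein id -> orthogroup id, for one genome."""
        out: dict[str, str] = {}
        for og, per_genome in self.members.items():
            for pid in per_genome.get(genome, ()):
                out[pid] = og
        return out


# ---------------------------------------------------------------------------
# low-level helpers


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# intensity + design


def read_design(path) -> SampleDesign:
    f = _read_tsv(path)
    required = {"sample_id", "timepoint", "replicate"}
    missing = required - set(f.columns)
    if missing:
        raise FormatError(f"design file lacks columns: {sorted(missing)}")
    try:
        f["timepoint"] = f["timepoint"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer timepoint in design: {exc}") from exc
    if "batch" not in f.columns or (f["batch"] == "").all():
        f["batch"] = f["replicate"]
    f = f.set_index("sample_id")
    return SampleDesign(f[["timepoint", "replicate", "batch"]])


def read_intensity_table(path, design_path, *, missing_sentinel: float | None = 0.0) -> IntensityMatrix:
    """Read a raw intensity TSV against its sample design.

    Cells that are empty, non-finite, or equal to ``missing_sentinel``
    (default 0, the MaxQuant unquantified-channel convention) become NaN.
    """
    design = read_design(design_path)
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError("intensity table needs a protein-id column and >=1 sample column")
    pid_col = raw.columns[0]
    ids = raw[pid_col]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate protein id: {dup.iloc[0]!r}")
    grid = raw.drop(columns=[pid_col]).replace("", np.nan)
    try:
        grid = grid.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity value: {exc}") from exc
    orphans = [s for s in grid.columns if s not in design.frame.index]
    if orphans:
        raise ValidationError(f"samples absent from design: {orphans}")
    if missing_sentinel is not None:
        grid = grid.mask(grid == missing_sentinel)
    grid.index = ids.tolist()
    return IntensityMatrix(grid, design.subset(list(grid.columns)), "raw")


def write_intensity_table(m: IntensityMatrix, path, design_path=None) -> None:
    out = m.values.copy()
    out.insert(0, "protein_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if design_path is not None:
        d = m.design.frame.copy()
        d.insert(0, "sample_id", d.index)
        d.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homology hit tables


def read_hit_table(path, taxon_map: dict[str, str] | None = None, *,
                   unmapped: str = "drop") -> pd.DataFrame:
    """Parse a 12-column tabular homology-search file.

    ``taxon_map`` assigns each subject id a taxon class (e.g. ``laby_hondaea``
    or ``other_stramenopile``); when given, a ``taxon_class`` column is added.
    Subjects missing from the map are handled per ``unmapped``: ``"drop"``
    removes the rows with a warning, ``"error"`` raises.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                rec = [
                    parts[0], parts[1], float(parts[2]), int(parts[3]), int(parts[4]),
                    int(parts[5]), int(parts[6]), int(parts[7]), int(parts[8]),
                    int(parts[9]), float(parts[10]), float(parts[11]),
                ]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: malformed numeric field ({exc})") from exc
            rows.append(rec)
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if not hits.empty and (hits["evalue"] < 0).any():
        raise ValidationError("negative e-value in hit table")
    if taxon_map is not None:
        hits["taxon_class"] = hits["subject"].map(taxon_map)
        unmappable = hits["taxon_class"].isna()
        if unmappable.any():
            if unmapped == "error":
                bad = hits.loc[unmappable, "subject"].unique().tolist()
                raise ValidationError(f"subjects without taxon class: {bad}")
            warnings.warn(f"dropped {int(unmappable.sum())} hit rows with unmapped subjects")
            hits = hits.loc[~unmappable].reset_index(drop=True)
    return hits


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# orthogroups


def read_orthogroups(path, genome_lineages: dict[str, str]) -> OrthogroupTable:
    """Read a wide orthogroup TSV (first column = orthogroup id, one column per
    genome, cells = comma-separated member ids)."""
    f = _read_tsv(path)
    if f.empty and f.shape[1] == 0:
        return OrthogroupTable(pd.DataFrame(), {}, dict(genome_lineages))
    og_col = f.columns[0]
    genomes = [c for c in f.columns if c != og_col]
    unlabeled = [g for g in genomes if g not in genome_lineages]
    if unlabeled:
        raise ValidationError(f"genomes without lineage label: {unlabeled}")
    members: dict[str, dict[str, tuple[str, ...]]] = {}
    counts = {}
    seen: dict[str, str] = {}
    for _, row in f.iterrows():
        og = row[og_col]
        per_genome = {}
        for g in genomes:
            ids = tuple(x.strip() for x in row[g].split(",") if x.strip())
            for pid in ids:
                if pid in seen:
                    raise ValidationError(
                        f"protein {pid!r} appears in orthogroups {seen[pid]!r} and {og!r}"
                    )
                seen[pid] = og
            per_genome[g] = ids
        members[og] = per_genome
        counts[og] = {g: len(per_genome[g]) for g in genomes}
    counts_df = pd.DataFrame.from_dict(counts, orient="index", dtype=int)
    counts_df = counts_df.reindex(columns=genomes) if counts else pd.DataFrame(columns=genomes, dtype=int)
    lineages = {g: genome_lineages[g] for g in genomes}
    return OrthogroupTable(counts_df, members, lineages)


def write_orthogroups(og: OrthogroupTable, path) -> None:
    genomes = list(og.counts.columns)
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(genomes) + "\n")
        for name in og.counts.index:
            cells = [",".join(og.members[name].get(g, ())) for g in genomes]
            fh.write(name + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# annotations


def read_annotation_map(path, namespace: str = "custom") -> AnnotationMap:
    f = _read_tsv(path)
    if f.shape[1] < 2:
        raise FormatError("annotation map needs two columns: protein_id, term")
    pid_col, term_col = f.columns[:2]
    terms: dict[str, set[str]] = {}
    for pid, term in zip(f[pid_col], f[term_col]):
        if not pid or not term:
            raise FormatError("empty protein id or term in annotation map")
        terms.setdefault(term, set()).add(pid)
    return AnnotationMap(namespace, terms)


def write_annotation_map(ann: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm\n")
        for term in sorted(ann.terms):
            for pid in sorted(ann.terms[term]):
                fh.write(f"{pid}\t{term}\n")
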