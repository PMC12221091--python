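"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a 5-timepoint x 3-replicate iTRAQ settlement time
course: log2-scale reporter intensities are baseline + planted temporal
effect + replicate batch offset + Gaussian noise, exponentiated to integer
intensity units.  Four temporal archetypes mirror the settlement clusters:

* C1 — high in zoospores, full step down from T2 on;
* C2 — high in zoospores, graded decline reaching the full effect by T6;
* C3 — low in zoospores, rising at T6/T8;
* C4 — low in zoospores, rising at T2 and staying up.

On top of the intensity matrix the generator plants lineage structure
(laby-restricted upregulated candidates, orphans, broadly conserved
decoys), emits homology hit tables for the lineage screen and for the
two-annotation reciprocal-best-hit merge, orthogroup tables in which every
planted candidate satisfies the four screen conditions (and controls
violate exactly one each where that is logically possible), and annotation
maps with one term enriched in a chosen archetype.

Every generator draws from its own named RNG stream derived from the single
config seed, so adding a generator never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import LABY, OTHER, AnnotationMap, IntensityMatrix, SampleDesign

ARCHETYPES = ("C1", "C2", "C3", "C4")
# per-archetype effect, in multiples of effect_size_log2, at T2, T4, T6, T8
ARCHETYPE_SHAPES = {
    "C1": (-1.0, -1.0, -1.0, -1.0),
    "C2": (-1.0 / 3.0, -2.0 / 3.0, -1.0, -1.0),
    "C3": (0.0, 0.0, 1.0, 1.0),
    "C4": (1.0, 1.0, 1.0, 1.0),
}
LINEAGE_CLASSES = ("laby_restricted", "stramenopile_shared", "orphan", "broad")

_STREAMS = {"intensities": 1, "hits": 2, "orthogroups": 3, "annotations": 4, "lineage": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic time course.

    Defaults mirror the real experiment where it pins them: 5 timepoints x
    3 replicates, baselines spanning the observed log2 intensity range
    11.8-24.4, archetype fractions proportional to the published cluster
    sizes, a 1 log2-unit planted effect.
    """

    n_proteins: int = 2000
    timepoints: tuple[int, ...] = (0, 2, 4, 6, 8)
    n_replicates: int = 3
    de_fraction_per_archetype: tuple[float, float, float, float] = (0.024, 0.047, 0.042, 0.052)
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.25
    batch_sd_log2: float = 0.3
    missing_rate: float = 0.02
    baseline_log2_range: tuple[float, float] = (11.8, 24.4)
    n_restricted: int = 12
    n_orphan: int = 5
    n_broad_decoys: int = 10
    bitscore_noise_sd: float = 0.0
    rbh_rate: float = 0.6
    n_terms: int = 20
    enriched_archetype: str = "C4"
    enrichment_odds: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.de_fraction_per_archetype
        if len(fracs) != 4 or any(not 0 <= f <= 1 for f in fracs):
            raise ValidationError("need 4 archetype fractions in [0, 1]")
        if sum(fracs) >= 1:
            raise ValidationError("archetype fractions must sum to < 1")
        lo, hi = self.baseline_log2_range
        if lo >= hi:
            raise ValidationError("baseline_log2_range must be ordered")
        for name, v in (("effect_size_log2", self.effect_size_log2),
                        ("noise_sd_log2", self.noise_sd_log2)):
            if v < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth: archetype, per-timepoint log2 effect, lineage class and
    orthogroup-condition flags per protein."""

    frame: pd.DataFrame  # indexed by protein_id

    @property
    def protein_ids(self) -> list[str]:
        return list(self.frame.index)

    def archetype_members(self, name: str) -> list[str]:
        return list(self.frame.index[self.frame["archetype"] == name])

    def de_proteins(self) -> list[str]:
        return list(self.frame.index[self.frame["archetype"] != ""])

    def planted_candidates(self) -> list[str]:
        return list(self.frame.index[self.frame["is_candidate"]])

    def write(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "protein_id", out.index)
        out.to_csv(path, sep="\t", index=False)


def _protein_ids(n: int) -> list[str]:
    return [f"A{i:06d}" for i in range(1, n + 1)]


def build_design(config: SimulationConfig) -> SampleDesign:
    rows = []
    for t in config.timepoints:
        for r in range(1, config.n_replicates + 1):
            rows.append({"sample_id": f"T{t}_{r}", "timepoint": t,
                         "replicate": str(r), "batch": str(r)})
    return SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


def _assign_truth(config: SimulationConfig) -> pd.DataFrame:
    """Archetype and lineage assignment (stream 'lineage')."""
    rng = _rng(config.seed, "lineage")
    ids = _protein_ids(config.n_proteins)
    archetype = np.full(config.n_proteins, "", dtype=object)
    counts = [int(round(f * config.n_proteins)) for f in config.de_fraction_per_archetype]
    start = 0
    for name, cnt in zip(ARCHETYPES, counts):
        archetype[start:start + cnt] = name
        start += cnt

    effects = np.zeros((config.n_proteins, len(config.timepoints) - 1))
    for i, a in enumerate(archetype):
        if a:
            effects[i] = np.array(ARCHETYPE_SHAPES[a]) * config.effect_size_log2

    # lineage classes: planted candidates and orphans come from the
    # post-settlement-upregulated archetypes (C3/C4); broad decoys likewise
    up_idx = np.flatnonzero((archetype == "C3") | (archetype == "C4"))
    need = config.n_restricted + config.n_orphan + config.n_broad_decoys
    if len(up_idx) < need:
        raise ValidationError(
            f"not enough upregulated proteins ({len(up_idx)}) to plant "
            f"{need} lineage-restricted/orphan/decoy proteins"
        )
    chosen = rng.choice(up_idx, size=need, replace=False)
    lineage = np.full(config.n_proteins, "", dtype=object)
    lineage[chosen[:config.n_restricted]] = "laby_restricted"
    lineage[chosen[config.n_restricted:config.n_restricted + config.n_orphan]] = "orphan"
    lineage[chosen[config.n_restricted + config.n_orphan:]] = "broad"
    rest = lineage == ""
    lineage[rest] = rng.choice(["broad", "stramenopile_shared"], size=int(rest.sum()),
                               p=[0.7, 0.3])

    frame = pd.DataFrame({
        "archetype": archetype,
        "lineage_class": lineage,
        "is_candidate": lineage == "laby_restricted",
    }, index=ids)
    for j, t in enumerate(config.timepoints[1:]):
        frame[f"effect_T{t}"] = effects[:, j]
    return frame


def simulate_intensities(config: SimulationConfig) -> tuple[IntensityMatrix, TruthTable]:
    """Raw intensity matrix + truth table; deterministic given config.seed."""
    design = build_design(config)
    truth_frame = _assign_truth(config)
    rng = _rng(config.seed, "intensities")

    n, tps = config.n_proteins, list(config.timepoints)
    baseline = rng.uniform(*config.baseline_log2_range, size=n)
    batch_offsets = rng.normal(0.0, config.batch_sd_log2, size=config.n_replicates)
    effect_cols = [f"effect_T{t}" for t in tps[1:]]
    effects = np.column_stack([np.zeros(n), truth_frame[effect_cols].to_numpy()])

    samples = design.sample_ids
    log2 = np.empty((n, len(samples)))
    for j, sid in enumerate(samples):
        t = design.frame.loc[sid, "timepoint"]
        r = int(design.frame.loc[sid, "replicate"]) - 1
        noise = rng.normal(0.0, config.noise_sd_log2, size=n) if config.noise_sd_log2 > 0 else 0.0
        log2[:, j] = baseline + effects[:, tps.index(t)] + batch_offsets[r] + noise

    raw = np.maximum(np.rint(np.exp2(log2)), 1.0)
    if config.missing_rate > 0:
        raw[rng.uniform(size=raw.shape) < config.missing_rate] = np.nan
    values = pd.DataFrame(raw, index=truth_frame.index, columns=samples)
    return IntensityMatrix(values, design, "raw"), TruthTable(truth_frame)


# ---------------------------------------------------------------------------
# homology hit tables


@dataclass
class SimulatedHits:
    """All homology tables the pipeline consumes, plus planted merge facts."""

    screen_hits: pd.DataFrame          # 12-column rows + taxon_class resolvable
    taxon_map: dict[str, str]
    hits_ab: pd.DataFrame
    hits_ba: pd.DataFrame
    ids_b: list[str]
    planted_rbh_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_ambiguous: set[str] = field(default_factory=set)


def _hit_row(query: str, subject: str, pident: float, evalue: float,
             bitscore: float) -> dict:
    return {
        "query": query, "subject": subject, "pident": round(float(pident), 1),
        "length": 200, "mismatch": 20, "gapopen": 2, "qstart": 1, "qend": 200,
        "sstart": 1, "send": 200, "evalue": float(evalue),
        "bitscore": round(float(bitscore), 1),
    }


def _evalue_for(bitscore: float) -> float:
    # monotone decreasing in bitscore; floor avoids literal zeros
    return float(max(10.0 ** (-bitscore / 10.0), 1e-180))


def simulate_hit_tables(truth: TruthTable, config: SimulationConfig) -> SimulatedHits:
    """Emit the lineage-screen hit table and the A<->B merge hit tables.

    Planted structure: laby-restricted proteins hit only Hondaea subjects;
    stramenopile-shared proteins get >= top-5 strong non-Hondaea hits and no
    Hondaea hit; orphans get none; broad proteins hit both classes, with the
    best-Hondaea minus best-other bitscore delta drawn high for background
    (non-upregulated) proteins and low for the upregulated decoys, so no
    decoy is Hondaea-like.  The merge tables plant mutual best hits for a
    ``rbh_rate`` fraction of ids, asymmetric decoy hits, and one
    many-to-one ambiguity.
    """
    rng = _rng(config.seed, "hits")
    noise = config.bitscore_noise_sd
    rows = []
    taxon_map: dict[str, str] = {}
    hon_i = oth_i = 0

    def hon_subject() -> str:
        nonlocal hon_i
        hon_i += 1
        s = f"HF_{hon_i:05d}"
        taxon_map[s] = "laby_hondaea"
        return s

    def oth_subject() -> str:
        nonlocal oth_i
        oth_i += 1
        s = f"ST_{oth_i:05d}"
        taxon_map[s] = "other_stramenopile"
        return s

    def jitter(b: float) -> float:
        return b + (rng.normal(0.0, noise) if noise > 0 else 0.0)

    f = truth.frame
    for pid, rec in f.iterrows():
        cls = rec["lineage_class"]
        if cls == "orphan":
            continue
        if cls == "laby_restricted":
            base = rng.uniform(90, 160)
            for d in (0.0, rng.uniform(10, 30)):
                b = jitter(base - d)
                rows.append(_hit_row(pid, hon_subject(), rng.uniform(40, 80),
                                     _evalue_for(b), b))
        elif cls == "stramenopile_shared":
            base = rng.uniform(150, 250)
            for d in range(6):
                b = jitter(base - 3 * d)
                rows.append(_hit_row(pid, oth_subject(), rng.uniform(50, 90),
                                     _evalue_for(b), b))
        elif cls == "broad":
            upregulated = rec["archetype"] in ("C3", "C4")
            best_other = rng.uniform(100, 200)
            delta = rng.uniform(-60, -30) if upregulated else rng.uniform(-30, 60)
            b_laby = jitter(best_other + delta)
            b_other = jitter(best_other)
            rows.append(_hit_row(pid, hon_subject(), rng.uniform(30, 70),
                                 _evalue_for(b_laby), b_laby))
            rows.append(_hit_row(pid, oth_subject(), rng.uniform(30, 70),
                                 _evalue_for(b_other), b_other))
            # weaker extra hits exercise top-N selection without changing bests
            extra = jitter(min(b_laby, b_other) - rng.uniform(5, 15))
            rows.append(_hit_row(pid, oth_subject(), rng.uniform(25, 60),
                                 _evalue_for(extra), extra))
    screen_hits = pd.DataFrame(rows)

    # --- merge hit tables -------------------------------------------------
    ids_a = truth.protein_ids
    n = len(ids_a)
    ids_b = [f"B{i:06d}" for i in range(1, n + 1)]
    n_pairs = int(round(config.rbh_rate * n))
    ab, ba = [], []
    pairs = set()
    for i in range(n_pairs):
        a, b = ids_a[i], ids_b[i]
        pairs.add((a, b))
        ab.append(_hit_row(a, b, 95.0, 1e-120, 220.0))
        ba.append(_hit_row(b, a, 95.0, 1e-120, 220.0))
        if i + 1 < n:  # weaker cross hit; never the best
            ab.append(_hit_row(a, ids_b[i + 1], 60.0, 1e-40, 90.0))

    # asymmetric decoys among unpaired ids: a -> b best, but b -> elsewhere
    unpaired_a = ids_a[n_pairs:]
    unpaired_b = ids_b[n_pairs:]
    ambiguous: set[str] = set()
    if len(unpaired_a) >= 3 and len(unpaired_b) >= 2:
        # two unpaired A queries share one best unpaired B target -> ambiguity
        target = unpaired_b[0]
        for a in unpaired_a[:2]:
            ab.append(_hit_row(a, target, 70.0, 1e-50, 120.0))
        ba.append(_hit_row(target, ids_a[0], 65.0, 1e-45, 110.0))
        ambiguous.add(target)
        # a one-directional hit with no reciprocation
        ab.append(_hit_row(unpaired_a[2], unpaired_b[1], 55.0, 1e-30, 80.0))
    return SimulatedHits(
        screen_hits=screen_hits, taxon_map=taxon_map,
        hits_ab=pd.DataFrame(ab), hits_ba=pd.DataFrame(ba),
        ids_b=ids_b, planted_rbh_pairs=pairs, planted_ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# orthogroups


GENOME_LINEAGES = {
    "Aurli": LABY, "Honfer": LABY, "Aplke": LABY, "Schagg": LABY, "Thrkin": LABY,
    "Phatri": OTHER, "Ectsil": OTHER, "Sacce": OTHER,
}


def simulate_orthogroups(truth: TruthTable, config: SimulationConfig):
    """Orthogroup table in which planted candidates satisfy the structural
    screen conditions and negative controls violate exactly one condition
    each (where logically possible: failing the >=2-laby-genomes condition
    forces losing the Hondaea copy too, since Hondaea is itself a
    Labyrinthulomycota genome).

    Returns (OrthogroupTable, genome_lineages); also records the planted
    per-condition flags in ``truth.frame`` (columns og_cond1..og_cond4).
    """
    from .io import OrthogroupTable  # local import avoids cycle at module load

    rng = _rng(config.seed, "orthogroups")
    f = truth.frame
    laby_extra = ["Aplke", "Schagg", "Thrkin"]
    members: dict[str, dict[str, tuple[str, ...]]] = {}
    cond = pd.DataFrame(False, index=f.index,
                        columns=["og_cond1", "og_cond2", "og_cond4"])
    counter = 0

    def add_og(pid: str | None, genomes_members: dict[str, list[str]]) -> None:
        nonlocal counter
        counter += 1
        name = f"OG{counter:07d}"
        members[name] = {g: tuple(v) for g, v in genomes_members.items() if v}

    controls_placed = {"cond2": False, "cond4": False}
    for pid, rec in f.iterrows():
        cls = rec["lineage_class"]
        upregulated = rec["archetype"] in ("C3", "C4")
        og_id = counter + 1
        if cls == "laby_restricted":
            gm = {"Aurli": [pid], "Honfer": [f"HFOG{og_id}_1"]}
            if rng.uniform() < 0.5:  # sometimes conserved in a third laby genome
                gm[laby_extra[0]] = [f"APOG{og_id}_1"]
            add_og(pid, gm)
            cond.loc[pid] = [True, True, True]
        elif cls == "orphan":
            continue  # no orthogroup: fails the laby-presence conditions
        elif cls == "broad" and upregulated and not controls_placed["cond4"]:
            # control: violates only the Hondaea-copy condition
            add_og(pid, {"Aurli": [pid], laby_extra[0]: [f"APOG{og_id}_1"]})
            cond.loc[pid] = [True, True, False]
            controls_placed["cond4"] = True
        elif cls == "broad" and upregulated and not controls_placed["cond2"]:
            # control: violates only the non-laby-count condition
            add_og(pid, {"Aurli": [pid], "Honfer": [f"HFOG{og_id}_1"],
                         "Phatri": [f"PTOG{og_id}_1"], "Ectsil": [f"ESOG{og_id}_1"]})
            cond.loc[pid] = [True, False, True]
            controls_placed["cond2"] = True
        elif cls in ("broad", "stramenopile_shared"):
            gm = {"Aurli": [pid],
                  "Phatri": [f"PTOG{og_id}_1"], "Ectsil": [f"ESOG{og_id}_1"],
                  "Sacce": [f"SCOG{og_id}_1"]}
            if cls == "broad":
                gm["Honfer"] = [f"HFOG{og_id}_1"]
                gm[laby_extra[1]] = [f"SGOG{og_id}_1"]
            add_og(pid, gm)
            cond.loc[pid] = [cls == "broad", False, cls == "broad"]
    counts = pd.DataFrame.from_dict(
        {og: {g: len(v) for g, v in per.items()} for og, per in members.items()},
        orient="index",
    ).reindex(columns=list(GENOME_LINEAGES), fill_value=0).fillna(0).astype(int)
    truth.frame[["og_cond1", "og_cond2", "og_cond4"]] = cond
    truth.frame["og_cond3"] = truth.frame["archetype"].isin(("C3", "C4"))
    return OrthogroupTable(counts, members, dict(GENOME_LINEAGES)), dict(GENOME_LINEAGES)


# ---------------------------------------------------------------------------
# annotations


def simulate_annotations(truth: TruthTable, config: SimulationConfig) -> AnnotationMap:
    """One annotation term per protein; the first term is enriched in the
    configured archetype at the configured odds ratio, the rest are uniform."""
    rng = _rng(config.seed, "annotations")
    terms = [f"KOG{i:02d}" for i in range(1, config.n_terms + 1)]
    enriched = terms[0]
    p_bg = 1.0 / config.n_terms
    odds = config.enrichment_odds
    if np.isinf(odds):
        p_fg = 1.0
        p_bg_enr = 0.0
    else:
        p_fg = odds * p_bg / (1 + (odds - 1) * p_bg)
        p_bg_enr = p_bg
    assignment: dict[str, set[str]] = {t: set() for t in terms}
    in_arch = truth.frame["archetype"] == config.enriched_archetype
    for pid, is_fg in zip(truth.frame.index, in_arch):
        p_enr = p_fg if is_fg else p_bg_enr
        if rng.uniform() < p_enr:
            assignment[enriched].add(pid)
        else:
            assignment[rng.choice(terms[1:])].add(pid)
    return AnnotationMap("KOG_class", {t: s for t, s in assignment.items() if s})


def simulate_all(config: SimulationConfig):
    """Convenience wrapper: every synthetic input in one call."""
    matrix, truth = simulate_intensities(config)
    hits = simulate_hit_tables(truth, config)
    orthogroups, lineages = simulate_orthogroups(truth, config)
    annotations = simulate_annotations(truth, config)
    return matrix, truth, hits, orthogroups, lineages, annotations
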