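"""Merging two predicted-proteome id spaces by reciprocal best hits.

Two gene-model sets for the same genome (e.g. a JGI annotation and an
MMETSP/UniProt annotation) are reduced to one non-redundant protein set:
pairs of reciprocal best hits collapse to a single entry keyed by the
A-space id (the B-space id kept as alias); everything unpaired enters on
its own, minus entries dropped by a deterministic ambiguity rule.  A
per-sample detection list in either id space then maps onto the merged set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


def best_hit_per_query(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: maximum bitscore, ties broken by lower
    e-value, then higher percent identity, then lexicographically smaller
    subject id."""
    if hits.empty:
        return {}
    ordered = hits.sort_values(
        by=["query", "bitscore", "evalue", "pident", "subject"],
        ascending=[True, False, True, False, True],
        kind="mergesort",
    )
    first = ordered.groupby("query", sort=False).head(1)
    return dict(zip(first["query"], first["subject"]))


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> set[tuple[str, str]]:
    """(a, b) pairs with best_A->B(a) = b and best_B->A(b) = a."""
    best_ab = best_hit_per_query(hits_ab)
    best_ba = best_hit_per_query(hits_ba)
    return {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}


@dataclass
class MergeMap:
    """Outcome of the two-annotation merge.

    ``nonredundant_ids`` are the primary keys of the merged set: the A-space
    id for RBH pairs and for unpaired A entries, the B-space id for unpaired
    B entries.  ``alias`` maps pair keys to their B-space partner.
    """

    rbh_pairs: set[tuple[str, str]]
    unpaired_a: set[str]
    unpaired_b: set[str]
    dropped_ambiguous: dict[str, str] = field(default_factory=dict)  # id -> reason
    nonredundant_ids: list[str] = field(default_factory=list)
    alias: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {
            "rbh_pairs": len(self.rbh_pairs),
            "unpaired_a": len(self.unpaired_a),
            "unpaired_b": len(self.unpaired_b),
            "dropped": len(self.dropped_ambiguous),
            "nonredundant": len(self.nonredundant_ids),
        }


def build_nonredundant(ids_a: list[str], ids_b: list[str],
                       pairs: set[tuple[str, str]],
                       hits_ab: pd.DataFrame | None = None,
                       hits_ba: pd.DataFrame | None = None,
                       drop_ambiguous: bool = True) -> MergeMap:
    """Assemble the non-redundant merged set.

    Entries: one per RBH pair (keyed by the A id), plus every unpaired id
    from either space.  When ``drop_ambiguous`` and the hit tables are
    supplied, an unpaired entry that is the best hit of >= 2 unpaired
    queries from the other space (a many-to-one conflict) is dropped and
    logged — the deterministic stand-in for removing ambiguous or redundant
    assignments.
    """
    set_a, set_b = set(ids_a), set(ids_b)
    if len(set_a) != len(ids_a) or len(set_b) != len(ids_b):
        raise ValidationError("duplicate ids within an id universe")
    for a, b in pairs:
        if a not in set_a:
            raise ValidationError(f"pair member {a!r} absent from id universe A")
        if b not in set_b:
            raise ValidationError(f"pair member {b!r} absent from id universe B")
    paired_a = {a for a, _ in pairs}
    paired_b = {b for _, b in pairs}
    if len(paired_a) != len(pairs) or len(paired_b) != len(pairs):
        raise ValidationError("an id occurs in more than one reciprocal pair")
    unpaired_a = set_a - paired_a
    unpaired_b = set_b - paired_b

    dropped: dict[str, str] = {}
    if drop_ambiguous and hits_ab is not None and hits_ba is not None:
        # unpaired entries targeted by >= 2 unpaired queries from the other space
        best_ab = best_hit_per_query(hits_ab)
        best_ba = best_hit_per_query(hits_ba)
        for unpaired_side, best_other, label in (
            (unpaired_b, {q: s for q, s in best_ab.items() if q in unpaired_a}, "B"),
            (unpaired_a, {q: s for q, s in best_ba.items() if q in unpaired_b}, "A"),
        ):
            targets = pd.Series(list(best_other.values())).value_counts()
            conflicted = set(targets.index[targets >= 2]) & unpaired_side
            for entry in sorted(conflicted):
                dropped[entry] = (
                    f"best hit of {int(targets[entry])} unpaired queries "
                    f"from the other annotation"
                )
                logger.info("dropped ambiguous %s-space entry %s (%s)",
                            label, entry, dropped[entry])
        unpaired_a -= set(dropped)
        unpaired_b -= set(dropped)

    alias = {a: b for a, b in pairs}
    nonredundant = sorted(paired_a) + sorted(unpaired_a) + sorted(unpaired_b)
    return MergeMap(
        rbh_pairs=set(pairs),
        unpaired_a=unpaired_a,
        unpaired_b=unpaired_b,
        dropped_ambiguous=dropped,
        nonredundant_ids=nonredundant,
        alias=alias,
    )


def map_detected(detected_a: set[str], detected_b: set[str], merge: MergeMap) -> set[str]:
    """Merged entries detected in either annotation's detection list."""
    out = set()
    for entry in merge.nonredundant_ids:
        partner = merge.alias.get(entry)
        if partner is not None:  # pair entry: detected if either member is
            if entry in detected_a or partner in detected_b:
                out.add(entry)
        elif entry in merge.unpaired_a:
            if entry in detected_a:
                out.add(entry)
        elif entry in merge.unpaired_b:
            if entry in detected_b:
                out.add(entry)
    return out


def write_merge_map(merge: MergeMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("entry_id\tkind\talias\treason\n")
        for a, b in sorted(merge.rbh_pairs):
            fh.write(f"{a}\trbh_pair\t{b}\t\n")
        for a in sorted(merge.unpaired_a):
            fh.write(f"{a}\tunpaired_a\t\t\n")
        for b in sorted(merge.unpaired_b):
            fh.write(f"{b}\tunpaired_b\t\t\n")
        for e, reason in sorted(merge.dropped_ambiguous.items()):
            fh.write(f"{e}\tdropped\t\t{reason}\n")
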