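"""Descriptive LCD statistics.

Counts per organism and class (proteins with ≥1 LCD, LCD instances, residues
occupied), organism-level class frequencies and rarity bins, per-residue
occupancy, secondary-class shares, eukaryote-/domain-specific classes,
co-occurrence combinations with reciprocal-class merging, spatial
distinctness of LCD pairs, and Pfam-clan concentration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classes import ALL_CLASS_LABELS, CANONICAL_AA, reciprocal_merged_label
from .errors import ConfigurationError, ConsistencyError
from .proteome import Proteome
from .scanner import LCD

COUNT_COLUMNS = ("n_proteins_with_lcd", "n_lcds", "n_lcd_residues")

RARITY_BINS = (
    ("absent", 0.0, 0.0),
    ("very rare", 0.0, 5.0),
    ("rare", 5.0, 20.0),
    ("normal", 20.0, 50.0),
    ("common", 50.0, 75.0),
    ("very common", 75.0, 100.0),
)


@dataclass
class ClassCountTable:
    """Per-class LCD tallies for one organism plus proteome totals."""

    proteome_id: str
    per_class: pd.DataFrame  # index class_label; columns COUNT_COLUMNS
    n_proteins_total: int
    n_residues_total: int
    domain_of_life: str = "Unknown"
    clade: str = ""

    def count(self, class_label: str, column: str) -> int:
        if class_label in self.per_class.index:
            return int(self.per_class.at[class_label, column])
        return 0


def _union_size(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def count_class_table(lcds: pd.DataFrame, proteome: Proteome) -> ClassCountTable:
    """Tally LCDs per class for one organism.

    ``n_lcd_residues`` counts each residue at most once per class: per
    protein, the union of that class's [start, end] intervals, summed over
    proteins.
    """
    known = set(proteome.accessions)
    rows = {}
    if len(lcds):
        unknown = set(lcds["accession"]) - known
        if unknown:
            raise ConsistencyError(
                f"LCD table references accessions absent from proteome "
                f"{proteome.proteome_id}: {sorted(unknown)[:5]}"
            )
        for label, sub in lcds.groupby("class_label", sort=True):
            n_prot = sub["accession"].nunique()
            n_lcds = len(sub)
            n_res = sum(
                _union_size(zip(g["start"], g["end"]))
                for _, g in sub.groupby("accession", sort=False)
            )
            rows[label] = (n_prot, n_lcds, n_res)
    per_class = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(COUNT_COLUMNS)
    ).astype(int)
    per_class.index.name = "class_label"
    return ClassCountTable(
        proteome_id=proteome.proteome_id,
        per_class=per_class.sort_index(),
        n_proteins_total=len(proteome),
        n_residues_total=proteome.n_residues,
        domain_of_life=proteome.domain_of_life,
        clade=proteome.clade,
    )


def organism_level_frequency(
    tables: Sequence[ClassCountTable],
    class_labels: Sequence[str] = ALL_CLASS_LABELS,
) -> pd.Series:
    """Percentage of organisms with ≥1 LCD of each class.

    ``tables`` is the group (one per organism — e.g. all eukaryotes); the
    denominator is the full group, including organisms with no LCDs at all.
    """
    if len(tables) == 0:
        raise ValueError("organism group is empty")
    n = len(tables)
    freqs = {
        lbl: 100.0 * sum(t.count(lbl, "n_proteins_with_lcd") >= 1 for t in tables) / n
        for lbl in class_labels
    }
    return pd.Series(freqs, name="pct_organisms")


def rarity_category(x: float) -> str:
    """Rarity bin of an organism-level percentage.

    absent (x = 0), very rare (0 < x < 5), rare (5 ≤ x < 20),
    normal (20 ≤ x < 50), common (50 ≤ x < 75), very common (x ≥ 75).
    """
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"percentage out of range: {x}")
    if x == 0.0:
        return "absent"
    if x < 5.0:
        return "very rare"
    if x < 20.0:
        return "rare"
    if x < 50.0:
        return "normal"
    if x < 75.0:
        return "common"
    return "very common"


def per_residue_occupancy(table: ClassCountTable, class_label: str) -> float:
    """Percentage of the proteome's residues inside the class's LCD union."""
    if table.n_residues_total <= 0:
        raise ValueError("empty proteome has no defined occupancy")
    return 100.0 * table.count(class_label, "n_lcd_residues") / table.n_residues_total


def secondary_share(table: ClassCountTable, primary_aa: str) -> pd.Series | None:
    """Within one primary amino acid, each secondary class's share (%) of all
    secondary LCDs with that primary. ``None`` when no such LCDs exist."""
    labels = [primary_aa + s for s in CANONICAL_AA if s != primary_aa]
    counts = np.array([table.count(lbl, "n_lcds") for lbl in labels], dtype=float)
    total = counts.sum()
    if total == 0:
        return None
    return pd.Series(100.0 * counts / total, index=labels, name="pct_share")


def domain_specific_classes(
    freqs: Mapping[str, pd.Series],
    target_domain: str,
    in_min: float = 15.0,
    out_max: float = 2.0,
) -> set[str]:
    """Classes found in >``in_min``% of the target domain's organisms but
    <``out_max``% of each other domain's (strict inequalities on both)."""
    if target_domain not in freqs:
        raise ConfigurationError(f"no frequencies for domain {target_domain!r}")
    others = [d for d in freqs if d != target_domain]
    if not others:
        raise ConfigurationError("need frequencies for at least two domains")
    target = freqs[target_domain]
    out = set()
    for lbl, v in target.items():
        if v > in_min and all(freqs[d].get(lbl, 0.0) < out_max for d in others):
            out.add(lbl)
    return out


def co_occurrence_counts(
    lcds: pd.DataFrame,
    class_filter: set[str] | None = None,
) -> dict[tuple[str, ...], int]:
    """UpSet-style exact-combination counts of LCD categories per protein.

    Reciprocal secondary classes (XY / YX) are collapsed to one canonical
    category before forming each protein's category set; identical sets are
    counted across proteins. Keys are sorted category tuples.
    """
    counter: Counter[tuple[str, ...]] = Counter()
    if not len(lcds):
        return {}
    sub = lcds
    if class_filter is not None:
        sub = lcds[lcds["class_label"].isin(class_filter)]
    for _, g in sub.groupby("accession", sort=False):
        cats = tuple(sorted({reciprocal_merged_label(c) for c in g["class_label"]}))
        if cats:
            counter[cats] += 1
    return dict(counter)


def spatially_distinct(lcd_a: LCD, lcd_b: LCD, min_outside: int = 20) -> bool:
    """True when ≥ ``min_outside`` residues of ``lcd_b`` lie outside the span
    of ``lcd_a``. Both LCDs must belong to the same protein."""
    if lcd_a.accession != lcd_b.accession:
        raise ValueError("spatial distinctness is defined within one protein")
    overlap = max(0, min(lcd_a.end, lcd_b.end) - max(lcd_a.start, lcd_b.start) + 1)
    outside = lcd_b.length - overlap
    return outside >= min_outside


def max_single_clan_share(
    class_proteins: set[str],
    clan_map: Mapping[str, object],
    min_n: int = 5,
) -> float | None:
    """Largest percentage of a class's Pfam-annotated proteins sharing one
    clan.

    Only proteins with ≥1 clan annotation enter the denominator; a protein
    mapped to several clans counts toward each. Returns ``None`` when fewer
    than ``min_n`` annotated proteins exist.
    """
    annotated = [p for p in class_proteins if clan_map.get(p)]
    if len(annotated) < min_n:
        return None
    clan_counts: Counter[str] = Counter()
    for p in annotated:
        clans = clan_map[p]
        if isinstance(clans, str):
            clans = [clans]
        for clan in set(clans):
            clan_counts[clan] += 1
    return 100.0 * max(clan_counts.values()) / len(annotated)
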