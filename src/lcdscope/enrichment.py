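"""Scrambled-proteome null model and LCD enrichment testing.

Each proteome is scrambled once with a seeded Fisher–Yates shuffle under
biological constraints: the initiator residue of every protein (typically
methionine) is held fixed, the remaining residues are pooled, shuffled and
re-segmented into the original protein lengths. For every LCD class, the
number of proteins containing ≥1 LCD in the original vs the scrambled
proteome forms a 2×2 table tested with Fisher's exact test (two-sided by
default); within an organism, p-values are Holm–Šidák adjusted across the
classes represented in either proteome. The natural log odds ratio with a
Woolf 95% CI summarizes effect size; when either with-LCD cell is zero, a +1
pseudocount on all cells yields a flagged, conservatively biased estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .classes import ClassSpec
from .errors import ConfigurationError
from .proteome import ProteinRecord, Proteome
from .scanner import scan_proteome

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class EnrichmentResult:
    """Original-vs-scrambled contingency outcome for one LCD class."""

    class_label: str
    a: int  # original proteins with >=1 LCD
    b: int  # original proteins without
    c: int  # scrambled proteins with >=1 LCD
    d: int  # scrambled proteins without
    p_raw: float
    p_adj: float
    ln_or: float
    ci_low: float
    ci_high: float
    biased: bool
    represented: bool
    significant: bool
    direction: str  # "enriched" | "depleted" | "none"


def scramble_proteome(proteome: Proteome, seed: int) -> Proteome:
    """Length-, composition- and initiator-preserving proteome scramble.

    Deterministic for a given seed (numpy PCG64 generator, in-place
    Fisher–Yates shuffle). Length-1 proteins contribute nothing to the pool
    and survive unchanged.
    """
    rng = np.random.default_rng(seed)
    pool = np.array([ch for p in proteome.proteins for ch in p.sequence[1:]])
    rng.shuffle(pool)
    out: list[ProteinRecord] = []
    offset = 0
    for p in proteome.proteins:
        n = len(p.sequence) - 1
        body = "".join(pool[offset:offset + n])
        offset += n
        out.append(ProteinRecord(p.accession, p.sequence[0] + body))
    return Proteome(
        proteome.proteome_id + "_scrambled", out,
        proteome.domain_of_life, proteome.clade,
    )


def _orient_smallest_margin(a: int, b: int, c: int, d: int) -> tuple[int, int, int, int]:
    # transposes / swaps leave the two-sided Fisher p unchanged; enumerate
    # over the smallest margin
    if min(a + b, c + d) > min(a + c, b + d):
        a, b, c, d = a, c, b, d  # transpose
    if a + b > c + d:
        a, b, c, d = c, d, a, b
    return a, b, c, d


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact probability, computed exactly.

    Enumerates the hypergeometric support with integer arithmetic (exact
    tie handling) and sums the probabilities of all tables at most as likely
    as the observed one. An all-zero table returns NaN.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return math.nan
    a, b, c, d = _orient_smallest_margin(a, b, c, d)
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # P(t) = C(r1,t)·C(r2,c1−t)/C(n,c1); compare numerators exactly
    numers = [math.comb(r1, t) * math.comb(r2, c1 - t) for t in range(lo, hi + 1)]
    obs = numers[a - lo]
    total = sum(numers)
    tail = sum(x for x in numers if x <= obs)
    return float(tail / total)


def ln_odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float, float, bool]:
    """lnOR with Woolf 95% CI; +1 pseudocount when either with-LCD cell is 0.

    Returns (lnOR, ci_low, ci_high, biased). The pseudocount is triggered
    only by a = 0 or c = 0 (the with-LCD cells); a zero in b or d after
    adjustment yields NaN markers.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    biased = a == 0 or c == 0
    if biased:
        a, b, c, d = a + 1, b + 1, c + 1, d + 1
    if b == 0 or d == 0:
        return math.nan, math.nan, math.nan, biased
    ln_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ln_or, ln_or - Z_95 * se, ln_or + Z_95 * se, biased


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    with np.errstate(divide="ignore"):  # p == 1 is legal and maps to 1
        return multipletests(p, method="holm-sidak")[1]


def sidak(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Single-step Šidák adjustment 1 − (1 − p)^m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    return -np.expm1(m * np.log1p(-p))


def tally_proteins_with_lcd(lcds: pd.DataFrame, class_label: str) -> int:
    if not len(lcds):
        return 0
    sub = lcds[lcds["class_label"] == class_label]
    return sub["accession"].nunique()


def enrichment_analysis(
    proteome: Proteome,
    lcds_orig: pd.DataFrame,
    seed: int,
    specs: Sequence[ClassSpec],
    alpha: float = 0.05,
    lcds_scrambled: pd.DataFrame | None = None,
) -> list[EnrichmentResult]:
    """Scramble once, rescan, and test every class for enrichment/depletion.

    Classes with zero LCD-containing proteins in both proteomes are
    *unrepresented*: carried through with NaN p-values, excluded from the
    Holm–Šidák family, never significant. ``lcds_scrambled`` may be supplied
    to reuse an existing scan of ``scramble_proteome(proteome, seed)``.
    """
    if not specs:
        raise ConfigurationError("no class specs supplied")
    if lcds_scrambled is None:
        scrambled = scramble_proteome(proteome, seed)
        lcds_scrambled = scan_proteome(scrambled, specs)
    n = len(proteome)
    orig_counts = (
        lcds_orig.groupby("class_label")["accession"].nunique()
        if len(lcds_orig) else pd.Series(dtype=int)
    )
    scr_counts = (
        lcds_scrambled.groupby("class_label")["accession"].nunique()
        if len(lcds_scrambled) else pd.Series(dtype=int)
    )
    rows = []
    for spec in specs:
        lbl = spec.label
        a = int(orig_counts.get(lbl, 0))
        c = int(scr_counts.get(lbl, 0))
        rows.append((lbl, a, n - a, c, n - c))
    represented = [r for r in rows if r[1] > 0 or r[3] > 0]
    p_raw = {r[0]: fisher_exact_2x2(r[1], r[2], r[3], r[4]) for r in represented}
    labels = [r[0] for r in represented]
    p_adj = dict(zip(labels, holm_sidak([p_raw[l] for l in labels]))) if labels else {}
    results = []
    for lbl, a, b, c, d in rows:
        rep = lbl in p_raw
        praw = p_raw.get(lbl, math.nan)
        padj = p_adj.get(lbl, math.nan)
        ln_or, lo, hi, biased = ln_odds_ratio(a, b, c, d)
        sig = rep and padj < alpha
        direction = "none"
        if sig and ln_or > 0:
            direction = "enriched"
        elif sig and ln_or < 0:
            direction = "depleted"
        results.append(EnrichmentResult(
            lbl, a, b, c, d, praw, padj, ln_or, lo, hi,
            biased, rep, sig, direction,
        ))
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def domain_enrichment_summary(
    results_by_organism: Mapping[str, Sequence[EnrichmentResult]],
    group: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per class: % of organisms significantly enriched / depleted and the
    median lnOR across the group.

    Denominators are all organisms in the group; classes unrepresented in an
    organism count as not significant there, and their (biased, zero) lnORs
    enter the median.
    """
    orgs = list(group) if group is not None else list(results_by_organism)
    if not orgs:
        raise ValueError("organism group is empty")
    per_class: dict[str, dict[str, list]] = {}
    for org in orgs:
        for r in results_by_organism[org]:
            slot = per_class.setdefault(
                r.class_label, {"enr": 0, "dep": 0, "lnors": []}
            )
            if r.significant and r.ln_or > 0:
                slot["enr"] += 1
            elif r.significant and r.ln_or < 0:
                slot["dep"] += 1
            if not math.isnan(r.ln_or):
                slot["lnors"].append(r.ln_or)
    n = len(orgs)
    rows = []
    for lbl in sorted(per_class):
        slot = per_class[lbl]
        rows.append({
            "class_label": lbl,
            "pct_enriched": 100.0 * slot["enr"] / n,
            "pct_depleted": 100.0 * slot["dep"] / n,
            "median_lnor": median(slot["lnors"]) if slot["lnors"] else math.nan,
        })
    return pd.DataFrame(rows).set_index("class_label")
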