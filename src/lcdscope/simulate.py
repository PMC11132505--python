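"""Self-contained synthetic fixtures for every pipeline stage.

Generates proteomes with configurable background amino-acid frequencies and
length distributions, plants LCDs of chosen classes with evenly interleaved
target residues (so composition *and* dispersion criteria are met by
construction), and emits miniature multi-organism "surveys" complete with a
toy GO ontology/annotation set carrying a planted class↔term association, a
Pfam-style clan map and a ground-truth table.

Background presets: ``uniform`` (1/20 each), ``swissprot`` (database-average
frequencies), and ``falciparum-like`` (strongly elevated N and K, emulating
the compositionally skewed *P. falciparum* proteome). Every source of
randomness flows through one seeded numpy generator per bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classes import CANONICAL_AA, spec_from_label
from .errors import ConfigurationError
from .proteome import ProteinRecord, Proteome, write_fasta

# Swiss-Prot database-average amino-acid frequencies (fractions).
_SWISSPROT = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


def _normalized(freqs: Mapping[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    if total <= 0 or any(v < 0 for v in freqs.values()):
        raise ConfigurationError("background frequencies must be a valid "
                                 "probability vector")
    return {aa: freqs.get(aa, 0.0) / total for aa in CANONICAL_AA}


def background_preset(name: str) -> dict[str, float]:
    """Named background frequency presets: uniform, swissprot,
    falciparum-like."""
    if name == "uniform":
        return {aa: 1 / 20 for aa in CANONICAL_AA}
    if name == "swissprot":
        return _normalized(_SWISSPROT)
    if name == "falciparum-like":
        skewed = dict(_SWISSPROT)
        skewed["N"] = 0.11
        skewed["K"] = 0.10
        skewed["I"] = 0.08
        skewed["E"] = 0.07
        return _normalized(skewed)
    raise ConfigurationError(f"unknown background preset {name!r}")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated proteome."""

    seed: int
    background_freqs: dict[str, float]
    n_proteins: int
    lengths: list[int]
    # (accession, class_label, start, end, primary_comp, secondary_comp)
    planted: list[tuple[str, str, int, int, float, float]] = field(default_factory=list)
    planted_go: tuple[str, str] | None = None  # (class_label, go_id)


def generate_background_proteome(
    n_proteins: int,
    length_distribution: tuple[int, int] | Sequence[int],
    background_freqs: Mapping[str, float],
    seed: int,
    proteome_id: str = "SYN000",
) -> tuple[Proteome, SyntheticTruth]:
    """i.i.d.-background proteome; every protein starts with M.

    ``length_distribution`` is either an inclusive (min, max) range sampled
    uniformly or an explicit length per protein.
    """
    freqs = _normalized(background_freqs)
    rng = np.random.default_rng(seed)
    if isinstance(length_distribution, tuple):
        lo, hi = length_distribution
        lengths = rng.integers(lo, hi + 1, size=n_proteins).tolist()
    else:
        if len(length_distribution) != n_proteins:
            raise ConfigurationError("explicit lengths must match n_proteins")
        lengths = [int(x) for x in length_distribution]
    if any(l < 1 for l in lengths):
        raise ConfigurationError("protein lengths must be >= 1")
    aas = np.array(list(CANONICAL_AA))
    probs = np.array([freqs[aa] for aa in CANONICAL_AA])
    proteins = []
    for i, L in enumerate(lengths):
        body = "".join(rng.choice(aas, size=L - 1, p=probs)) if L > 1 else ""
        proteins.append(ProteinRecord(f"{proteome_id}_P{i + 1:05d}", "M" + body))
    truth = SyntheticTruth(seed, freqs, n_proteins, lengths)
    return Proteome(proteome_id, proteins), truth


def _even_positions(n: int, slots: Sequence[int]) -> list[int]:
    """n positions spread as evenly as possible across ``slots``."""
    m = len(slots)
    return [slots[(i * m) // n] for i in range(n)]


def plant_lcd(
    proteome: Proteome,
    truth: SyntheticTruth,
    accession: str,
    class_label: str,
    start: int,
    length: int,
    primary_comp: float,
    secondary_comp: float = 0.0,
    seed: int = 0,
) -> None:
    """Overwrite [start, start+length−1] (1-based) with a planted LCD.

    Target residues are interleaved as evenly as possible so that every
    window within the region meets both the composition and the dispersion
    criteria; filler residues are drawn from the background excluding the
    target amino acids. Residues outside the interval are untouched.
    """
    spec = spec_from_label(class_label)
    protein = proteome.get(accession)
    end = start + length - 1
    if start < 1 or end > len(protein.sequence):
        raise ConfigurationError(
            f"planted interval ({start}, {end}) outside protein "
            f"{accession} of length {len(protein.sequence)}"
        )
    rng = np.random.default_rng(seed)
    n_p = max(1, math.ceil(primary_comp * length))
    region = [""] * length
    p_pos = _even_positions(n_p, list(range(length)))
    for i in p_pos:
        region[i] = spec.primary_aa
    n_s = 0
    if spec.secondary_aa is not None:
        n_s = max(1, math.ceil(secondary_comp * length))
        free = [i for i in range(length) if not region[i]]
        for i in _even_positions(n_s, free):
            region[i] = spec.secondary_aa
    filler_aas = [aa for aa in CANONICAL_AA
                  if aa not in (spec.primary_aa, spec.secondary_aa)]
    bg = np.array([truth.background_freqs.get(aa, 0.0) for aa in filler_aas])
    bg = bg / bg.sum() if bg.sum() > 0 else np.full(len(filler_aas), 1 / len(filler_aas))
    free = [i for i in range(length) if not region[i]]
    fill = rng.choice(np.array(filler_aas), size=len(free), p=bg)
    for i, ch in zip(free, fill):
        region[i] = ch
    seq = protein.sequence
    protein.sequence = seq[:start - 1] + "".join(region) + seq[end:]
    truth.planted.append((
        accession, class_label, start, end,
        n_p / length, n_s / length if spec.secondary_aa else float("nan"),
    ))


@dataclass
class PlantProfile:
    """How one LCD class is planted within one domain of life."""

    class_label: str
    organism_fraction: float = 1.0  # fraction of the domain's organisms
    protein_fraction: float = 0.1   # fraction of proteins per planted organism
    primary_comp: float = 0.55
    secondary_comp: float = 0.30
    length: int = 40


@dataclass
class StudyConfig:
    """Configuration of a miniature multi-organism survey."""

    organisms_per_domain: dict[str, int] = field(default_factory=lambda: {
        "Archaea": 5, "Bacteria": 5, "Eukaryota": 5, "Viruses": 5,
    })
    n_proteins: int = 30
    length_range: tuple[int, int] = (80, 200)
    background: dict[str, str] = field(default_factory=lambda: {
        "Archaea": "swissprot", "Bacteria": "swissprot",
        "Eukaryota": "swissprot", "Viruses": "uniform",
    })
    planted: dict[str, list[PlantProfile]] = field(default_factory=lambda: {
        "Eukaryota": [PlantProfile("Q", 1.0, 0.2), PlantProfile("HQ", 1.0, 0.1)],
        "Bacteria": [PlantProfile("Q", 0.6, 0.1)],
        "Archaea": [PlantProfile("Q", 0.4, 0.1)],
        "Viruses": [],
    })
    # (class_label, domain) receiving the planted GO association
    go_association: tuple[str, str] | None = ("HQ", "Eukaryota")
    go_term: str = "GO:1000004"


_CLADES = {
    "Archaea": "Euryarchaeota", "Bacteria": "Proteobacteria",
    "Eukaryota": "Metazoa", "Viruses": "Riboviria",
}


@dataclass
class StudyBundle:
    """In-memory handle on a generated survey plus its on-disk layout."""

    out_dir: Path
    proteomes: dict[str, Proteome]
    truths: dict[str, SyntheticTruth]
    metadata: dict[str, tuple[str, str]]
    fasta_paths: dict[str, Path]
    obo_path: Path | None
    gaf_paths: dict[str, Path]
    clan_path: Path
    truth_path: Path
    go_term: str | None
    go_class: str | None


def _write_toy_obo(path: Path, planted_term: str, n_decoys: int = 6) -> None:
    """Minimal BP ontology: root chain to depth 3, planted + decoy terms at
    depth 4."""
    lines = [
        "format-version: 1.2", "ontology: lcdscope-toy", "",
        "[Term]", "id: GO:0008150", "name: biological_process",
        "namespace: biological_process", "",
    ]
    chain = ["GO:1000001", "GO:1000002", "GO:1000003"]
    parent = "GO:0008150"
    for i, t in enumerate(chain, 1):
        lines += ["[Term]", f"id: {t}", f"name: toy level {i} process",
                  "namespace: biological_process", f"is_a: {parent}", ""]
        parent = t
    lines += ["[Term]", f"id: {planted_term}", "name: planted toy process",
              "namespace: biological_process", f"is_a: {parent}", ""]
    for i in range(1, n_decoys + 1):
        lines += ["[Term]", f"id: GO:200000{i}", f"name: decoy process {i}",
                  "namespace: biological_process", f"is_a: {parent}", ""]
    path.write_text("\n".join(lines) + "\n")


def _gaf_row(accession: str, go_id: str) -> str:
    fields = ["SYN", accession, accession, "involved_in", go_id,
              "SYN:0000001", "IEA", "", "P", "", "", "protein",
              "taxon:32644", "20260101", "lcdscope", "", ""]
    return "\t".join(fields)


def generate_study(
    config: StudyConfig,
    out_dir: str | Path,
    seed: int,
) -> StudyBundle:
    """Generate and write a complete miniature survey bundle.

    Deterministic for a given (config, seed): FASTA per organism, metadata
    TSV, toy OBO, one GAF per organism, a clan TSV and a ground-truth TSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    proteomes: dict[str, Proteome] = {}
    truths: dict[str, SyntheticTruth] = {}
    metadata: dict[str, tuple[str, str]] = {}
    fasta_paths: dict[str, Path] = {}
    gaf_paths: dict[str, Path] = {}
    clan_rows: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    go_class = go_domain = None
    if config.go_association is not None:
        go_class, go_domain = config.go_association

    for domain in sorted(config.organisms_per_domain):
        n_orgs = config.organisms_per_domain[domain]
        freqs = background_preset(config.background.get(domain, "swissprot"))
        profiles = config.planted.get(domain, [])
        for k in range(n_orgs):
            pid = f"SYN{domain[:3].upper()}{k + 1:03d}"
            org_seed = int(master.integers(0, 2**31 - 1))
            proteome, truth = generate_background_proteome(
                config.n_proteins, config.length_range, freqs, org_seed, pid,
            )
            proteome.domain_of_life = domain
            proteome.clade = _CLADES[domain]
            org_rng = np.random.default_rng(org_seed + 1)
            planted_accs_by_class: dict[str, list[str]] = {}
            for prof in profiles:
                if k >= round(prof.organism_fraction * n_orgs):
                    continue
                n_plant = max(1, round(prof.protein_fraction * config.n_proteins))
                eligible = [p.accession for p in proteome.proteins
                            if len(p.sequence) >= prof.length + 2]
                chosen = org_rng.choice(eligible, size=min(n_plant, len(eligible)),
                                        replace=False)
                for acc in chosen:
                    L = len(proteome.get(acc).sequence)
                    start = int(org_rng.integers(2, L - prof.length + 2))
                    plant_lcd(proteome, truth, acc, prof.class_label, start,
                              prof.length, prof.primary_comp,
                              prof.secondary_comp,
                              seed=int(org_rng.integers(0, 2**31 - 1)))
                    planted_accs_by_class.setdefault(prof.class_label, []).append(acc)
            proteomes[pid] = proteome
            truths[pid] = truth
            metadata[pid] = (domain, _CLADES[domain])
            fasta_paths[pid] = out_dir / f"{pid}.fasta"
            write_fasta(proteome, fasta_paths[pid])
            for acc, lbl, s, e, pc, sc in truth.planted:
                truth_rows.append((pid, acc, lbl, s, e, pc, sc, org_seed))

            # annotations: planted class proteins carry the planted term;
            # background proteins get decoy terms at random
            gaf_lines = ["!gaf-version: 2.2"]
            planted_set = set(planted_accs_by_class.get(go_class, [])) \
                if domain == go_domain else set()
            for p in proteome.proteins:
                if p.accession in planted_set:
                    gaf_lines.append(_gaf_row(p.accession, config.go_term))
                    truths[pid].planted_go = (go_class, config.go_term)
                if org_rng.random() < 0.5:
                    decoy = f"GO:200000{int(org_rng.integers(1, 7))}"
                    gaf_lines.append(_gaf_row(p.accession, decoy))
            gaf_paths[pid] = out_dir / f"{pid}.gaf"
            gaf_paths[pid].write_text("\n".join(gaf_lines) + "\n")

            # Pfam-style clans: planted proteins concentrate in one clan
            for p in proteome.proteins:
                in_planted = any(p.accession in v
                                 for v in planted_accs_by_class.values())
                if in_planted:
                    clan_rows.append((p.accession, "CL0001"))
                elif org_rng.random() < 0.5:
                    clan_rows.append(
                        (p.accession, f"CL000{int(org_rng.integers(2, 6))}"))

    meta_path = out_dir / "metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("proteome_id\tdomain_of_life\tlineage\n")
        for pid in sorted(metadata):
            dom, clade = metadata[pid]
            fh.write(f"{pid}\t{dom}\t{dom}; {clade}\n")

    obo_path = None
    if config.go_association is not None:
        obo_path = out_dir / "go.obo"
        _write_toy_obo(obo_path, config.go_term)

    clan_path = out_dir / "clans.tsv"
    with open(clan_path, "w") as fh:
        fh.write("accession\tclan\n")
        for acc, clan in sorted(clan_rows):
            fh.write(f"{acc}\t{clan}\n")

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("proteome_id\taccession\tclass_label\tstart\tend\t"
                 "primary_comp\tsecondary_comp\tseed\n")
        for row in sorted(truth_rows):
            fh.write("\t".join(str(x) for x in row) + "\n")

    return StudyBundle(out_dir, proteomes, truths, metadata, fasta_paths,
                       obo_path, gaf_paths, clan_path, truth_path,
                       config.go_term if config.go_association else None,
                       go_class)
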