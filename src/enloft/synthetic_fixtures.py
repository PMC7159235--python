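"""Deterministic miniature input universe for the whole pipeline.

From a seed and a parameter block this module emits every external input
the pipeline consumes — enhancer BED, regulation network TSV, gene-gene
interaction TSV, deletion VCF with per-sample genotypes, exon and
conserved-element BEDs, GIS and conservation tables, enhancer FASTA with
planted motifs, a JASPAR-style PWM file, a disease-enhancer table — plus a
ground-truth manifest of each enhancer's class.

The class-conditional structure mirrors what is observed in real data:
tolerant-like enhancers are tissue-specific (low ETU/EOD/EGTU), target
dispensable genes, sit in deletions carried homozygously by healthy
samples, and are weakly conserved; low-tolerance-like enhancers are the
reverse and reciprocally overlap ultraconserved elements. ``signal_strength``
scales the separation: 0 makes every class-conditional distribution
identical (pure noise), larger values pull them apart.

All output is synthetic; no external data is bundled or downloaded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import DeletionCall, GenomicInterval

#: Roadmap-like tissue group names; the four class-preferred groups first.
TISSUE_GROUPS = [
    "hsc_b_cell", "blood_t_cell", "brain", "kidney", "adipose",
    "digestive", "epithelial", "es_cell", "es_derived", "heart",
    "liver", "lung", "muscle", "neurosph", "thymus",
    "smooth_muscle", "spleen", "pancreas", "skin",
]

MOTIF_POU_LIKE = "TTATGCAAAT"  # octamer-class consensus planted in low-like
MOTIF_CONTROL = "GCGCGCGC"

CLASS_TOLERANT = "tolerant"
CLASS_LOW = "low"
CLASS_BACKGROUND = "background"
CLASS_HOLDOUT = "tolerant_holdout"

_SLOT_MARGIN = 500  # bp kept free on each side of an enhancer inside its slot


@dataclass(frozen=True)
class FixtureSpec:
    """Parameter block controlling the synthetic universe."""

    n_enhancers: int = 2000
    n_genes: int = 600
    n_tissues: int = 15
    n_samples: int = 60
    frac_tolerant: float = 0.10
    frac_low: float = 0.04
    frac_tolerant_holdout: float = 0.02
    signal_strength: float = 3.0
    genome_length: int = 10_000_000
    n_chroms: int = 2
    min_enhancer_length: int = 200
    max_enhancer_length: int = 2000
    background_deletions_per_enhancer: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_enhancers, self.n_genes, self.n_samples, self.n_chroms) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_tissues < 4:
            raise ValueError("need at least the 4 class-preferred tissue groups")
        if self.n_tissues > len(TISSUE_GROUPS):
            raise ValueError(f"at most {len(TISSUE_GROUPS)} tissue groups available")
        total = self.frac_tolerant + self.frac_low + self.frac_tolerant_holdout
        if total > 1.0:
            raise ValueError("class fractions exceed 1")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        per_chrom = math.ceil(self.n_enhancers / self.n_chroms)
        slot = self.genome_length // per_chrom
        if slot < self.max_enhancer_length + 2 * _SLOT_MARGIN + 200:
            raise ValueError(
                "geometrically unsatisfiable: too many enhancers for the genome length"
            )

    @property
    def tissues(self) -> list[str]:
        return TISSUE_GROUPS[: self.n_tissues]

    @property
    def slot_size(self) -> int:
        return self.genome_length // math.ceil(self.n_enhancers / self.n_chroms)


@dataclass
class UniverseBundle:
    """Paths of the emitted files plus the ground-truth manifest."""

    out_dir: Path
    paths: dict[str, Path]
    manifest: dict[str, str]  # enhancer id -> true class
    sample_populations: dict[str, str]
    tissue_map: dict[str, str]

    def ids_of(self, cls: str) -> list[str]:
        return [e for e, c in self.manifest.items() if c == cls]


@dataclass
class _Enh:
    id: str
    chrom: str
    start: int
    end: int
    cls: str
    slot_start: int
    slot_end: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def _assign_classes(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    n = spec.n_enhancers
    n_tol = round(spec.frac_tolerant * n)
    n_low = round(spec.frac_low * n)
    n_hold = round(spec.frac_tolerant_holdout * n)
    classes = (
        [CLASS_TOLERANT] * n_tol
        + [CLASS_LOW] * n_low
        + [CLASS_HOLDOUT] * n_hold
        + [CLASS_BACKGROUND] * (n - n_tol - n_low - n_hold)
    )
    return [classes[i] for i in rng.permutation(n)]


def _place_enhancers(spec: FixtureSpec, rng: np.random.Generator) -> list[_Enh]:
    classes = _assign_classes(spec, rng)
    slot = spec.slot_size
    per_chrom = math.ceil(spec.n_enhancers / spec.n_chroms)
    out = []
    for i in range(spec.n_enhancers):
        chrom = f"chr{i % spec.n_chroms + 1}"
        slot_idx = i // spec.n_chroms
        if slot_idx >= per_chrom:  # pragma: no cover - guarded by spec check
            raise ValueError("slot overflow")
        slot_start = slot_idx * slot
        length = int(rng.integers(spec.min_enhancer_length, spec.max_enhancer_length + 1))
        offset = int(rng.integers(_SLOT_MARGIN, slot - length - _SLOT_MARGIN + 1))
        start = slot_start + offset
        out.append(
            _Enh(
                id=f"{chrom}:{start}-{start + length}",
                chrom=chrom,
                start=start,
                end=start + length,
                cls=classes[i],
                slot_start=slot_start,
                slot_end=slot_start + slot,
            )
        )
    return out


def _gene_pools(spec: FixtureSpec, rng: np.random.Generator):
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    perm = rng.permutation(spec.n_genes)
    k = max(1, spec.n_genes // 10)
    dispensable = [genes[i] for i in perm[:k]]
    indispensable = [genes[i] for i in perm[k : 2 * k]]
    return genes, dispensable, indispensable


def _draw_gis(spec, rng, genes, dispensable, indispensable) -> dict[str, float]:
    s = spec.signal_strength
    gis = {}
    disp, indisp = set(dispensable), set(indispensable)
    for g in genes:
        if g in disp:
            v = rng.beta(2, 2 + 2 * s)
        elif g in indisp:
            v = rng.beta(2 + 2 * s, 2)
        else:
            v = rng.beta(2, 2)
        gis[g] = float(np.clip(v, 0.0, 1.0))
    return gis


_CLASS_EOD_LAMBDA = {
    CLASS_TOLERANT: lambda s: 2.0 / (1.0 + s),
    CLASS_HOLDOUT: lambda s: 2.0 / (1.0 + s),
    CLASS_LOW: lambda s: 2.0 * (1.0 + 0.5 * s),
    CLASS_BACKGROUND: lambda s: 2.0,
}
_CLASS_EDGE_LAMBDA = {
    CLASS_TOLERANT: lambda s: 0.8 / (1.0 + s),
    CLASS_HOLDOUT: lambda s: 0.8 / (1.0 + s),
    CLASS_LOW: lambda s: 0.8 + 1.2 * s,
    CLASS_BACKGROUND: lambda s: 0.8,
}
_CLASS_PREFERRED_TISSUES = {
    CLASS_TOLERANT: ("hsc_b_cell", "blood_t_cell"),
    CLASS_HOLDOUT: ("hsc_b_cell", "blood_t_cell"),
    CLASS_LOW: ("brain", "kidney"),
}


def _draw_edges(spec, rng, enhancers, genes, dispensable, indispensable):
    """Per-enhancer regulation edges with class-conditional tissue sets."""
    s = spec.signal_strength
    tissues = spec.tissues
    w = s / (1.0 + s)  # probability of drawing the class-matched gene pool
    p_pref = min(0.85, 0.25 + 0.15 * s)
    edges: list[tuple[str, str, tuple[str, ...]]] = []
    for enh in enhancers:
        lam = _CLASS_EOD_LAMBDA[enh.cls](s)
        eod = 1 + int(rng.poisson(lam))
        if enh.cls in (CLASS_TOLERANT, CLASS_HOLDOUT):
            pool = dispensable if rng.random() < w else genes
        elif enh.cls == CLASS_LOW:
            pool = indispensable if rng.random() < w else genes
        else:
            pool = genes
        eod = min(eod, len(pool))
        targets = [pool[i] for i in rng.choice(len(pool), size=eod, replace=False)]
        preferred = _CLASS_PREFERRED_TISSUES.get(enh.cls)
        for gene in targets:
            k = 1 + int(rng.poisson(_CLASS_EDGE_LAMBDA[enh.cls](s)))
            k = min(k, spec.n_tissues)
            chosen: list[str] = []
            if preferred is not None and rng.random() < p_pref:
                chosen.append(preferred[int(rng.integers(len(preferred)))])
            remaining = [t for t in tissues if t not in chosen]
            extra = k - len(chosen)
            if extra > 0:
                chosen += [
                    remaining[i]
                    for i in rng.choice(len(remaining), size=extra, replace=False)
                ]
            edges.append((enh.id, gene, tuple(sorted(chosen[:k]))))
    return edges


def _draw_interactions(spec, rng, genes, indispensable):
    s = spec.signal_strength
    weights = np.array([1.0 + s if g in set(indispensable) else 1.0 for g in genes])
    p = weights / weights.sum()
    kinds = sorted({"protein-protein", "metabolic", "phosphorylation", "signaling"})
    seen: set[tuple[str, str]] = set()
    rows = []
    target = 2 * spec.n_genes
    attempts = 0
    while len(rows) < target and attempts < 20 * target:
        attempts += 1
        i, j = rng.choice(len(genes), size=2, replace=False, p=p)
        g1, g2 = genes[int(i)], genes[int(j)]
        key = (min(g1, g2), max(g1, g2))
        if key in seen:
            continue
        seen.add(key)
        rows.append((g1, g2, kinds[int(rng.integers(len(kinds)))]))
    return rows


def _place_exons(spec, rng, enhancers) -> list[GenomicInterval]:
    """One short exon near the slot start of ~30% of non-tolerant slots.

    Tolerant and holdout slots stay exon-free so their covering deletions
    never touch coding sequence.
    """
    exons = []
    for enh in enhancers:
        if enh.cls in (CLASS_TOLERANT, CLASS_HOLDOUT):
            continue
        if rng.random() < 0.3:
            exons.append(GenomicInterval(enh.chrom, enh.slot_start + 50, enh.slot_start + 200))
    return exons


def _genotype_row(rng, n_samples, pops, base_f, hom_allowed=True, force_hom=False):
    """Per-sample genotype codes from an allele frequency with an AFR boost."""
    codes = []
    for s in range(n_samples):
        f = min(0.95, base_f * (1.4 if pops[s] == "AFR" else 1.0))
        dosage = int(rng.binomial(2, f))
        if not hom_allowed:
            dosage = min(dosage, 1)
        codes.append(("0/0", "0/1", "1/1")[dosage])
    if force_hom and "1/1" not in codes:
        codes[int(rng.integers(n_samples))] = "1/1"
    return codes


def _draw_deletions(spec, rng, enhancers, exons, sample_ids, pops):
    """Base deletion calls: tolerant-covering hom deletions plus decoys."""
    calls: list[DeletionCall] = []
    exon_slots = {(e.chrom, e.start // spec.slot_size * spec.slot_size) for e in exons}

    def pad(limit_lo: int, limit_hi: int) -> tuple[int, int]:
        return (
            int(rng.integers(50, min(400, limit_lo) + 1)),
            int(rng.integers(50, min(400, limit_hi) + 1)),
        )

    counter = 0

    def add(chrom, start, end, codes):
        nonlocal counter
        counter += 1
        genotypes = dict(zip(sample_ids, codes))
        call = DeletionCall(
            interval=GenomicInterval(chrom, start, end),
            genotypes=genotypes,
            allele_frequency=None,
            id=f"DEL{counter:06d}",
        )
        call.allele_frequency = call.carrier_frequency()
        calls.append(call)

    for enh in enhancers:
        if enh.cls != CLASS_TOLERANT:
            continue
        lo, hi = pad(enh.start - enh.slot_start - 50, enh.slot_end - enh.end - 50)
        f = 0.1 + 0.4 * rng.beta(2, 3)
        codes = _genotype_row(rng, spec.n_samples, pops, f, force_hom=True)
        add(enh.chrom, enh.start - lo, enh.end + hi, codes)

    n_bg = int(spec.background_deletions_per_enhancer * spec.n_enhancers)
    non_holdout = [e for e in enhancers if e.cls != CLASS_HOLDOUT]
    for _ in range(n_bg):
        enh = non_holdout[int(rng.integers(len(non_holdout)))]
        kind = rng.random()
        f = float(rng.beta(1.5, 8))
        if kind < 0.4:
            # fully covers an enhancer, but het-only: never hom-filtered in
            lo, hi = pad(enh.start - enh.slot_start - 50, enh.slot_end - enh.end - 50)
            codes = _genotype_row(rng, spec.n_samples, pops, f, hom_allowed=False)
            add(enh.chrom, enh.start - lo, enh.end + hi, codes)
        elif kind < 0.8 or (enh.chrom, enh.slot_start) not in exon_slots:
            # hom allowed, but starts inside the enhancer: partial overlap only
            start = enh.start + max(1, (enh.end - enh.start) // 2)
            end = enh.end + int(rng.integers(50, 400))
            codes = _genotype_row(rng, spec.n_samples, pops, f)
            add(enh.chrom, start, min(end, enh.slot_end - 50), codes)
        else:
            # overlaps the slot's exon: removed by the coding filter
            start = enh.slot_start + 20
            end = start + int(rng.integers(180, 380))
            codes = _genotype_row(rng, spec.n_samples, pops, f)
            add(enh.chrom, start, end, codes)

    # invariant: hom, exon-free deletions fully contain only tolerant enhancers
    tolerant_ids = {e.id for e in enhancers if e.cls == CLASS_TOLERANT}
    for call in calls:
        if not call.hom_samples():
            continue
        if any(call.interval.overlap(x) > 0 for x in exons):
            continue
        contained = {e.id for e in enhancers if call.interval.contains(e.interval)}
        assert contained <= tolerant_ids, "fixture would mislabel a non-tolerant enhancer"
    return calls


def write_vcf(
    path: Path,
    calls: Sequence[DeletionCall],
    sample_ids: Sequence[str],
    contig_lengths: Mapping[str, int],
) -> None:
    """Write symbolic ``<DEL>`` records (POS = 0-based start + 1, END = end)."""
    gt_out = {"0/0": "0|0", "0/1": "0|1", "1/1": "1|1", "./.": ".|."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for call in sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start)):
            iv = call.interval
            af = call.allele_frequency if call.allele_frequency is not None else 0.0
            info = f"SVTYPE=DEL;END={iv.end};AF={af:.6f}"
            gts = "\t".join(gt_out[call.genotypes[s]] for s in sample_ids)
            fh.write(
                f"{iv.chrom}\t{iv.start + 1}\t{call.id}\tN\t<DEL>\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def _conserved_elements(spec, rng, enhancers):
    """BED rows: reciprocally-overlapping elements for low-class enhancers,
    partial-overlap decoys, and reporter-negative elements."""
    rows = []
    for enh in enhancers:
        length = enh.end - enh.start
        if enh.cls == CLASS_LOW:
            shift = int(rng.integers(-length // 5, length // 5 + 1))
            dstart = max(enh.slot_start, enh.start + shift)
            dend = min(enh.slot_end, enh.end + int(rng.integers(-length // 5, length // 5 + 1)))
            elem = GenomicInterval(enh.chrom, dstart, max(dend, dstart + 1))
            ov = elem.overlap(enh.interval)
            if ov / length <= 0.5 or ov / elem.length <= 0.5:
                elem = enh.interval  # degenerate jitter: fall back to exact copy
            rows.append((elem, "uce_positive"))
        elif enh.cls == CLASS_BACKGROUND and rng.random() < 0.01:
            shift = int(0.75 * length)
            elem = GenomicInterval(enh.chrom, enh.start + shift, enh.end + shift)
            rows.append((elem, "uce_positive"))  # <50% overlap: must not label
        elif enh.cls == CLASS_BACKGROUND and rng.random() < 0.01:
            rows.append((enh.interval, "uce_negative"))  # reporter-negative
    return rows


def _conservation_scores(spec, rng, enhancers) -> dict[str, float]:
    s = spec.signal_strength
    out = {}
    for enh in enhancers:
        if enh.cls in (CLASS_TOLERANT, CLASS_HOLDOUT):
            v = rng.beta(1.2, 6 * (1 + 0.5 * s))
        elif enh.cls == CLASS_LOW:
            v = rng.beta(1.2 + 1.5 * s, 6 / (1 + 0.5 * s))
        else:
            v = rng.beta(1.2, 6)
        out[enh.id] = float(np.clip(v, 0.0, 1.0))
    return out


def _sequences(spec, rng, enhancers) -> dict[str, str]:
    s = spec.signal_strength
    bases = np.array(list("ACGT"))
    out = {}
    p_plant_low = min(0.9, 0.2 + 0.2 * s)
    for enh in enhancers:
        length = enh.end - enh.start
        seq = bases[rng.integers(0, 4, size=length)]
        plant = (
            p_plant_low if enh.cls == CLASS_LOW else 0.05
        )
        if length > len(MOTIF_POU_LIKE) + 2 and rng.random() < plant:
            pos = int(rng.integers(0, length - len(MOTIF_POU_LIKE)))
            seq[pos : pos + len(MOTIF_POU_LIKE)] = list(MOTIF_POU_LIKE)
        out[enh.id] = "".join(seq)
    return out


def _write_pwms(path: Path) -> None:
    def block(name: str, consensus: str) -> str:
        lines = [f">{name} {name}"]
        for base in "ACGT":
            counts = ["91" if c == base else "3" for c in consensus]
            lines.append(f"{base} [ " + " ".join(counts) + " ]")
        return "\n".join(lines) + "\n"

    with open(path, "w") as fh:
        fh.write(block("POUX", MOTIF_POU_LIKE))
        fh.write(block("CTRL", MOTIF_CONTROL))


def _disease_table(spec, rng, enhancers, edges):
    targets: dict[str, list[str]] = {}
    for eid, gene, _ in edges:
        targets.setdefault(eid, []).append(gene)
    pool = [e for e in enhancers if e.cls in (CLASS_LOW, CLASS_BACKGROUND)]
    n = min(30, len(pool))
    chosen = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    types = ["neurological", "skin", "obesity", "developmental", "cancer"]
    rows = []
    for enh in chosen:
        length = enh.end - enh.start
        if rng.random() < 0.7:  # overlapping record
            start = enh.start + int(rng.integers(0, max(1, length // 3)))
            end = min(enh.end + int(rng.integers(0, length // 3 + 1)), enh.slot_end)
        else:  # nearby, non-overlapping: matched via nearest-enhancer rule
            start = max(enh.slot_start, enh.start - 450)
            end = max(start + 50, enh.start - 350)
        gene_pool = targets.get(enh.id, [])
        if gene_pool and rng.random() < 0.8:
            gene = gene_pool[int(rng.integers(len(gene_pool)))]
        else:
            gene = f"G{int(rng.integers(spec.n_genes)) + 1:04d}"
        rows.append(
            (enh.chrom, start, end, gene, types[int(rng.integers(len(types)))])
        )
    return rows


def generate_universe(spec: FixtureSpec, out_dir: str | Path) -> UniverseBundle:
    """Emit the full synthetic input bundle; byte-identical under one seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    enhancers = _place_enhancers(spec, rng)
    genes, dispensable, indispensable = _gene_pools(spec, rng)
    gis = _draw_gis(spec, rng, genes, dispensable, indispensable)
    edges = _draw_edges(spec, rng, enhancers, genes, dispensable, indispensable)
    interactions = _draw_interactions(spec, rng, genes, indispensable)
    exons = _place_exons(spec, rng, enhancers)
    sample_ids = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    populations = ["AFR", "EUR", "EAS"]
    pops = [populations[i % 3] for i in range(spec.n_samples)]
    deletions = _draw_deletions(spec, rng, enhancers, exons, sample_ids, pops)
    conserved = _conserved_elements(spec, rng, enhancers)
    conservation = _conservation_scores(spec, rng, enhancers)
    sequences = _sequences(spec, rng, enhancers)
    disease = _disease_table(spec, rng, enhancers, edges)

    paths = {name: out / fname for name, fname in [
        ("enhancers", "enhancers.bed"), ("network", "network.tsv"),
        ("interactions", "interactions.tsv"), ("deletions", "deletions.vcf"),
        ("exons", "exons.bed"), ("conserved", "conserved.bed"),
        ("gis", "gis.tsv"), ("conservation", "conservation.tsv"),
        ("sequences", "sequences.fa"), ("pwms", "pwms.jaspar"),
        ("disease", "disease.tsv"), ("manifest", "manifest.tsv"),
        ("samples", "samples.tsv"), ("tissue_map", "tissue_map.json"),
    ]}

    with open(paths["enhancers"], "w") as fh:
        for e in enhancers:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\n")

    with open(paths["network"], "w") as fh:
        for i, (eid, gene, tissues) in enumerate(edges):
            for t in tissues:
                fh.write(f"{eid}${gene}\t{t}\n")
            if i < 5:  # decoy rows with an unmapped raw label, dropped on read
                fh.write(f"{eid}${gene}\tungrouped_cell\n")

    with open(paths["interactions"], "w") as fh:
        fh.write("# gene_a\tgene_b\ttype\n")
        for g1, g2, kind in interactions:
            fh.write(f"{g1}\t{g2}\t{kind}\n")
        # indirect-interaction decoys, excluded by the reader's whitelist
        if len(genes) >= 4:
            fh.write(f"{genes[0]}\t{genes[1]}\tgenetic\n")
            fh.write(f"{genes[2]}\t{genes[3]}\tregulatory\n")

    contigs = {f"chr{c + 1}": spec.genome_length for c in range(spec.n_chroms)}
    write_vcf(paths["deletions"], deletions, sample_ids, contigs)

    with open(paths["exons"], "w") as fh:
        for x in sorted(exons):
            fh.write(f"{x.chrom}\t{x.start}\t{x.end}\n")

    with open(paths["conserved"], "w") as fh:
        for elem, flag in sorted(conserved, key=lambda r: r[0]):
            fh.write(f"{elem.chrom}\t{elem.start}\t{elem.end}\t{flag}\n")

    with open(paths["gis"], "w") as fh:
        for g in genes:
            if rng.random() < 0.97:  # a few genes lack a score, as in real inputs
                fh.write(f"{g}\t{gis[g]:.6f}\n")

    with open(paths["conservation"], "w") as fh:
        for e in enhancers:
            fh.write(f"{e.id}\t{conservation[e.id]:.6f}\n")

    with open(paths["sequences"], "w") as fh:
        for e in enhancers:
            fh.write(f">{e.id}\n{sequences[e.id]}\n")

    _write_pwms(paths["pwms"])

    with open(paths["disease"], "w") as fh:
        fh.write("# chrom\tstart\tend\ttarget_gene\tdisease_type\n")
        for chrom, start, end, gene, dtype in disease:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\t{dtype}\n")

    manifest = {e.id: e.cls for e in enhancers}
    with open(paths["manifest"], "w") as fh:
        fh.write("# enhancer_id\tclass\n")
        for e in enhancers:
            fh.write(f"{e.id}\t{e.cls}\n")

    with open(paths["samples"], "w") as fh:
        fh.write("# sample\tpopulation\n")
        for s, p in zip(sample_ids, pops):
            fh.write(f"{s}\t{p}\n")

    tissue_map = {t: t for t in spec.tissues}
    with open(paths["tissue_map"], "w") as fh:
        json.dump(tissue_map, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return UniverseBundle(
        out_dir=out,
        paths=paths,
        manifest=manifest,
        sample_populations=dict(zip(sample_ids, pops)),
        tissue_map=tissue_map,
    )


def _overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return max(ov / a.length, ov / b.length)


def generate_pacbio_like_deletions(
    spec: FixtureSpec,
    bundle: UniverseBundle,
    max_base_overlap: float = 0.8,
) -> tuple[Path, list[str]]:
    """Emit a VCF of novel long-read-style deletions for three new samples.

    Every emitted deletion overlaps every base deletion by less than
    *max_base_overlap* (fraction of either interval). Deletions covering
    the held-out tolerant-like enhancers are carried homozygously, so
    those enhancers become newly discoverable. Returns the VCF path and
    the ids of enhancers newly fully deleted.
    """
    from .genomic_io import read_bed, read_deletions

    rng = np.random.default_rng(spec.seed + 1)
    base = read_deletions(bundle.paths["deletions"]).calls
    base_by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in base:
        base_by_chrom.setdefault(c.interval.chrom, []).append(c.interval)
    enh_records = read_bed(bundle.paths["enhancers"])
    by_id = {r.name: r.interval for r in enh_records}
    holdout = bundle.ids_of(CLASS_HOLDOUT)
    samples = ["PB001", "PB002", "PB003"]
    pops = ["EUR", "EUR", "AFR"]

    calls: list[DeletionCall] = []
    newly_deleted: list[str] = []
    counter = 0

    def admissible(iv: GenomicInterval) -> bool:
        return all(
            _overlap_fraction(iv, b) < max_base_overlap
            for b in base_by_chrom.get(iv.chrom, [])
        )

    for eid in holdout:
        iv = by_id[eid]
        lo = int(rng.integers(50, 400))
        hi = int(rng.integers(50, 400))
        novel = GenomicInterval(iv.chrom, max(0, iv.start - lo), iv.end + hi)
        if not admissible(novel):  # pragma: no cover - holdout slots lack base calls
            continue
        counter += 1
        codes = _genotype_row(rng, len(samples), pops, 0.5, force_hom=True)
        call = DeletionCall(novel, dict(zip(samples, codes)), None, f"PBDEL{counter:05d}")
        call.allele_frequency = call.carrier_frequency()
        calls.append(call)
        newly_deleted.append(eid)

    # extra novel background deletions placed in slot margins
    slot = spec.slot_size
    for _ in range(30):
        chrom = f"chr{int(rng.integers(spec.n_chroms)) + 1}"
        slot_idx = int(rng.integers(spec.genome_length // slot))
        start = slot_idx * slot + int(rng.integers(0, 300))
        novel = GenomicInterval(chrom, start, start + int(rng.integers(100, 450)))
        if not admissible(novel):
            continue
        counter += 1
        codes = _genotype_row(rng, len(samples), pops, 0.3)
        call = DeletionCall(novel, dict(zip(samples, codes)), None, f"PBDEL{counter:05d}")
        call.allele_frequency = call.carrier_frequency()
        calls.append(call)

    out_path = bundle.out_dir / "pacbio_deletions.vcf"
    contigs = {f"chr{c + 1}": spec.genome_length for c in range(spec.n_chroms)}
    write_vcf(out_path, calls, samples, contigs)
    with open(bundle.out_dir / "pacbio_novel_enhancers.tsv", "w") as fh:
        fh.write("# enhancer_id\n")
        for eid in newly_deleted:
            fh.write(eid + "\n")
    return out_path, newly_deleted
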