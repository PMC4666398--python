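"""Synthetic annotation bundles and read sets with planted Alu exonisation.

Each simulated gene carries two constitutive exons, a terminal exon whose
3' end is the genuine polyA cleavage site, and — for event genes — an
antisense Alu element in the downstream intergenic region hosting an Alu
exon at a log-uniformly sampled distance (41 bp – 21.4 kb by default,
matching the observed envelope of intergenic exonisation distances).
Reads are emitted for two conditions (control / knockdown) at the planted
inclusion levels; a truth table records every planted quantity the
pipeline is expected to recover.

The novel polyA site used upon exonisation is recorded in the truth table
but deliberately kept out of the genuine polyA track: "intergenic" is
defined relative to the annotated sites, which real annotation would not
extend with the cryptic cleavage product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AlignedRead, GeneModel, GenomicInterval, Transcript
from .io import AnnotationBundle

SCENARIO_NAMES = ("terminal_exon_skipping", "cryptic_5ss", "both")

#: Illumina Body Map 2.0-style tissue panel used for the FPKM matrices
TISSUES = (
    "adrenal", "thyroid", "heart", "testis", "adipose", "skeletal_muscle",
    "white_blood_cells", "brain", "lung", "liver", "colon", "ovary",
    "breast", "prostate", "kidney", "lymph_node",
)

SLOT = 30_000  # genomic space reserved per gene; exceeds every planted extent
GENES_PER_CHROM = 8


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the defaults the tests assume."""

    n_genes: int = 200
    fraction_with_events: float = 0.5
    #: probabilities of (terminal_exon_skipping, cryptic_5ss, both)
    scenario_mix: tuple[float, float, float] = (0.45, 0.37, 0.18)
    #: log-uniform envelope of polyA-to-Alu-exon distances, bp
    distance_bounds: tuple[int, int] = (41, 21_400)
    read_depth: int = 500
    read_length: int = 75
    inclusion_control: tuple[float, float] = (0.0, 0.15)
    inclusion_kd: tuple[float, float] = (0.10, 0.80)
    #: probability that an event gains >= 1 cryptic exon further downstream
    p_downstream_cryptic: float = 0.262
    p_second_cryptic: float = 0.25
    #: weight of the skipping structure within the "both" scenario mixture
    both_mix: float = 0.5
    p_extra_polya: float = 0.3
    p_decoy_alu: float = 0.3
    p_second_transcript: float = 0.25
    n_tissues: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.scenario_mix) - 1.0) > 1e-9:
            raise ValueError("scenario_mix must sum to 1")
        for p in (self.fraction_with_events, *self.scenario_mix):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_tissues > len(TISSUES):
            raise ValueError(f"at most {len(TISSUES)} tissues available")


@dataclass
class PlantedEvent:
    """Ground truth for one gene's planted exonisation event."""

    gene_id: str
    scenario: str  # terminal_exon_skipping | cryptic_5ss | both | none
    alu_interval: Optional[GenomicInterval] = None  # the antisense element
    alu_exon: Optional[GenomicInterval] = None
    distance_bp: Optional[int] = None
    inclusion_control: float = 0.0
    inclusion_kd: float = 0.0
    n_downstream_cryptic_exons: int = 0
    cryptic_donor: Optional[int] = None  # boundary inside the terminal exon
    cryptic_exons: tuple[GenomicInterval, ...] = ()
    novel_polya: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scenario == "none":
            if self.inclusion_control or self.inclusion_kd:
                raise ValueError("scenario=none implies zero inclusion")
        elif self.distance_bp is not None and self.distance_bp < 1:
            raise ValueError("distance_bp must be >= 1")


# ---------------------------------------------------------------------------
# annotation generation


def _reflect(iv: tuple[int, int], origin: int) -> tuple[int, int]:
    """Mirror a slot-relative half-open interval for minus-strand genes."""
    s, e = iv
    return (origin + SLOT - e, origin + SLOT - s)


def _place(iv: tuple[int, int], origin: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return (origin + iv[0], origin + iv[1])
    return _reflect(iv, origin)


def _interval(chrom: str, rel: tuple[int, int], origin: int, strand: str, name=None):
    s, e = _place(rel, origin, strand)
    return GenomicInterval(chrom, s, e, strand, name=name)


def generate_annotation(
    config: SimulationConfig,
) -> tuple[AnnotationBundle, list[PlantedEvent]]:
    """Build the annotation bundle and the planted-event truth list.

    Deterministic for a fixed config (seed included).  Gene geometry is
    laid out in fixed-size slots so planted intervals can never collide;
    minus-strand genes are coordinate reflections of the plus-strand
    layout, which exercises every strand-aware code path symmetrically.
    """
    rng = np.random.default_rng(config.seed)
    bundle = AnnotationBundle()
    events: list[PlantedEvent] = []
    lo, hi = config.distance_bounds

    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        origin = (i % GENES_PER_CHROM) * SLOT
        strand = "+" if i % 2 == 0 else "-"

        # slot-relative plus layout (reflected for minus-strand genes)
        rel_e1 = (1000, 1200)
        rel_e2 = (1800, 2000)
        rel_term = (2600, 3200)
        e1 = _interval(chrom, rel_e1, origin, strand)
        e2 = _interval(chrom, rel_e2, origin, strand)
        term = _interval(chrom, rel_term, origin, strand)
        gene = GeneModel(gene_id=gid)
        gene.transcripts.append(Transcript(f"{gid}.t1", (e1, e2, term)))
        if rng.random() < config.p_second_transcript:
            rel_e1b = (1050, 1200)  # alternative TSS variant of the first exon
            e1b = _interval(chrom, rel_e1b, origin, strand)
            gene.transcripts.append(Transcript(f"{gid}.t2", (e1b, e2, term)))
        gene.polya_sites.append(term.three_prime)
        if rng.random() < config.p_extra_polya:
            # a tandem genuine site upstream within the terminal exon
            upstream_rel = 3000
            pos = origin + upstream_rel if strand == "+" else origin + SLOT - 1 - upstream_rel
            gene.polya_sites.append(pos)
        bundle.genes[gid] = gene
        bundle.predicted_exons.extend(gene.exons)

        is_event = rng.random() < config.fraction_with_events
        if not is_event:
            if rng.random() < config.p_decoy_alu:
                rel_alu = (5000, 5300)  # silent antisense element, never exonised
                anti = "-" if strand == "+" else "+"
                s, e = _place(rel_alu, origin, strand)
                bundle.alu_elements.append(
                    GenomicInterval(chrom, s, e, anti, name=f"AluDecoy_{gid}")
                )
            events.append(PlantedEvent(gene_id=gid, scenario="none"))
            continue

        scenario = SCENARIO_NAMES[
            rng.choice(3, p=np.asarray(config.scenario_mix, dtype=float))
        ]
        distance = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        distance = max(lo, min(distance, hi))

        # place event intervals relative to the genuine polyA cleavage base so
        # that the gene-proximal Alu exon boundary sits exactly `distance`
        # downstream on either strand
        polya = term.three_prime
        alu_len, margin = 150, 40
        if strand == "+":
            alu_exon = GenomicInterval(chrom, polya + distance, polya + distance + alu_len, strand)
            elem = (alu_exon.start - margin, alu_exon.end + margin)
        else:
            alu_exon = GenomicInterval(chrom, polya - distance - alu_len, polya - distance, strand)
            elem = (alu_exon.start - margin, alu_exon.end + margin)
        anti = "-" if strand == "+" else "+"
        alu_elem = GenomicInterval(chrom, elem[0], elem[1], anti, name=f"AluY_{gid}")
        bundle.alu_elements.append(alu_elem)
        bundle.predicted_exons.append(alu_exon)

        n_cryp = 0
        if rng.random() < config.p_downstream_cryptic:
            n_cryp = 2 if rng.random() < config.p_second_cryptic else 1
        cryp_exons = []
        for j in range(n_cryp):
            if strand == "+":
                cs = alu_exon.end + 300 + j * 420
                cryp_exons.append(GenomicInterval(chrom, cs, cs + 120, strand))
            else:
                ce = alu_exon.start - 300 - j * 420
                cryp_exons.append(GenomicInterval(chrom, ce - 120, ce, strand))
        bundle.predicted_exons.extend(cryp_exons)

        cryptic_donor = None
        if scenario in ("cryptic_5ss", "both"):
            rel_c = 2900  # 300 nt into the 600-nt terminal exon
            cryptic_donor = origin + rel_c if strand == "+" else origin + SLOT - rel_c

        last_exon = cryp_exons[-1] if cryp_exons else alu_exon
        novel_polya = (
            last_exon.end + 150 if strand == "+" else last_exon.start - 1 - 150
        )

        events.append(
            PlantedEvent(
                gene_id=gid,
                scenario=scenario,
                alu_interval=alu_elem,
                alu_exon=alu_exon,
                distance_bp=distance,
                inclusion_control=float(rng.uniform(*config.inclusion_control)),
                inclusion_kd=float(rng.uniform(*config.inclusion_kd)),
                n_downstream_cryptic_exons=n_cryp,
                cryptic_donor=cryptic_donor,
                cryptic_exons=tuple(cryp_exons),
                novel_polya=novel_polya,
            )
        )
    return bundle, events


def chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    n_chroms = (config.n_genes + GENES_PER_CHROM - 1) // GENES_PER_CHROM
    return {f"chr{c + 1}": GENES_PER_CHROM * SLOT for c in range(n_chroms)}


# ---------------------------------------------------------------------------
# read simulation


def _isoform_chains(
    gene: GeneModel, event: PlantedEvent
) -> dict[str, list[GenomicInterval]]:
    """Exon chains in transcription order for every isoform the gene can emit."""
    tx = gene.transcripts[0]
    exons = list(tx.exons) if gene.strand == "+" else list(reversed(tx.exons))
    e1, e2, term = exons
    chains = {"canonical": [e1, e2, term]}
    if event.scenario == "none":
        return chains
    # cryptic_exons are generated progressively downstream, i.e. already in
    # transcription order on either strand
    cryp = list(event.cryptic_exons)
    if event.scenario in ("terminal_exon_skipping", "both"):
        chains["alu_skip"] = [e1, e2, event.alu_exon, *cryp]
    if event.scenario in ("cryptic_5ss", "both"):
        c = event.cryptic_donor
        trunc = (
            GenomicInterval(term.chrom, term.start, c, term.strand)
            if gene.strand == "+"
            else GenomicInterval(term.chrom, c, term.end, term.strand)
        )
        chains["alu_cryptic"] = [e1, e2, trunc, event.alu_exon, *cryp]
    return chains


def _read_blocks(
    chain: Sequence[GenomicInterval], t0: int, length: int
) -> tuple[GenomicInterval, ...]:
    """Map a transcript-coordinate window [t0, t0+length) onto genomic blocks."""
    blocks = []
    offset = 0
    hi = t0 + length
    for exon in chain:
        n = len(exon)
        lo_t = max(t0, offset)
        hi_t = min(hi, offset + n)
        if lo_t < hi_t:
            if exon.strand == "+":
                gs = exon.start + (lo_t - offset)
                ge = exon.start + (hi_t - offset)
            else:
                ge = exon.end - (lo_t - offset)
                gs = exon.end - (hi_t - offset)
            blocks.append(GenomicInterval(exon.chrom, gs, ge, exon.strand))
        offset += n
    return tuple(sorted(blocks, key=lambda b: b.start))


def _systematic_starts(n: int, n_positions: int, rng: np.random.Generator) -> list[int]:
    """n start positions on a randomly offset uniform lattice over [0, n_positions).

    Marginally uniform; consecutive starts are at most ceil(n_positions/n)
    apart, so every junction of an expressed isoform is spanned once a
    handful of reads are drawn.
    """
    if n == 0:
        return []
    u = rng.random()
    return [int((i + u) * n_positions / n) for i in range(n)]


def simulate_reads(
    bundle: AnnotationBundle,
    events: Sequence[PlantedEvent],
    config: SimulationConfig,
    condition: str,
    rng: Optional[np.random.Generator] = None,
) -> list[AlignedRead]:
    """Draw reads for one condition ("control" or "kd").

    Each read picks the Alu-derived isoform with probability equal to the
    planted inclusion for the condition (Bernoulli per read), then aligns
    an exact ``read_length`` window of the chosen isoform; windows that
    cross exon boundaries become junction-spanning reads.
    """
    if condition not in ("control", "kd"):
        raise ValueError("condition must be 'control' or 'kd'")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1 if condition == "kd" else 0])
        )
    L = config.read_length
    reads: list[AlignedRead] = []
    for event in events:
        gene = bundle.genes[event.gene_id]
        chains = _isoform_chains(gene, event)
        p = event.inclusion_kd if condition == "kd" else event.inclusion_control
        n_total = config.read_depth
        n_alu = int(rng.binomial(n_total, p)) if event.scenario != "none" else 0
        batches: list[tuple[str, int]] = [("canonical", n_total - n_alu)]
        if event.scenario == "both":
            n_skip = int(rng.binomial(n_alu, config.both_mix))
            batches += [("alu_skip", n_skip), ("alu_cryptic", n_alu - n_skip)]
        elif event.scenario == "terminal_exon_skipping":
            batches.append(("alu_skip", n_alu))
        elif event.scenario == "cryptic_5ss":
            batches.append(("alu_cryptic", n_alu))
        for iso_name, n in batches:
            if n == 0:
                continue
            chain = chains[iso_name]
            iso_len = sum(len(e) for e in chain)
            n_positions = iso_len - L + 1
            if n_positions < 1:
                raise ValueError(
                    f"read_length {L} exceeds isoform length {iso_len} of {event.gene_id}"
                )
            for k, t0 in enumerate(_systematic_starts(n, n_positions, rng)):
                blocks = _read_blocks(chain, t0, L)
                reads.append(
                    AlignedRead(
                        f"{event.gene_id}_{condition}_{iso_name}_{k}",
                        gene.chrom,
                        gene.strand,
                        blocks,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# FPKM matrices


def generate_fpkm_matrix(
    events: Sequence[PlantedEvent],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-isoform, per-tissue FPKM values with known relative abundance.

    Event genes get one Alu-exon-containing isoform plus 1–3 canonical
    isoforms.  Per-tissue relative abundance of the Alu group is a
    Beta-perturbed version of the gene's base inclusion (a 2-component
    Dirichlet); the exact planted per-tissue values are returned as a
    truth frame.  A small fraction of gene/tissue cells is zeroed out to
    exercise the undefined (0/0) path.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tissues = list(TISSUES[: config.n_tissues])
    rows = []
    truth_rows = []
    conc = 10.0
    for event in events:
        if event.scenario == "none":
            continue
        n_other = int(rng.integers(1, 4))
        p0 = min(max(event.inclusion_kd, 0.02), 0.98)
        alu_row = {
            "gene_id": event.gene_id,
            "isoform_id": f"{event.gene_id}.alu",
            "contains_alu_exon": True,
        }
        other_rows = [
            {
                "gene_id": event.gene_id,
                "isoform_id": f"{event.gene_id}.c{j}",
                "contains_alu_exon": False,
            }
            for j in range(n_other)
        ]
        for tissue in tissues:
            if rng.random() < 0.05:
                total = 0.0
                r = math.nan
            else:
                total = float(rng.lognormal(mean=2.0, sigma=1.0))
                r = float(rng.beta(conc * p0, conc * (1 - p0)))
            alu_row[tissue] = total * (0.0 if math.isnan(r) else r)
            split = rng.dirichlet(np.ones(n_other))
            for j, row in enumerate(other_rows):
                row[tissue] = total * (1 - (0.0 if math.isnan(r) else r)) * float(split[j])
            truth_rows.append(
                {"gene_id": event.gene_id, "tissue": tissue, "relative_abundance": r}
            )
        rows.append(alu_row)
        rows.extend(other_rows)
    cols = ["gene_id", "isoform_id", "contains_alu_exon", *tissues]
    fpkm = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "tissue", "relative_abundance"])
    return fpkm, truth


# ---------------------------------------------------------------------------
# toy ortholog pairs


def toy_ortholog_pair(
    extension: bool,
    alu_flagged: bool,
    post_conserved: bool,
    strand: str = "+",
    gene_id: str = "HTOY",
    mirror_at: int = 10_000,
):
    """Fabricate an ortholog pair with a known filter verdict.

    Three structural factors: a human transcript extending beyond the
    conserved terminal exon; an Alu-derived exon in the extension (when
    there is no extension, the Alu flag lands on an internal exon — a
    genuine intragenic exonisation, which must not satisfy the
    downstream criterion); and a conserved exon after the Alu exon.
    Only the (extension, Alu, no-post-conserved) combination passes.
    Minus-strand pairs are exact coordinate mirrors of the plus layout.
    """
    from .orthologs import OrthologPair

    def iv(s: int, e: int, chrom: str = "hchr1") -> GenomicInterval:
        if strand == "+":
            return GenomicInterval(chrom, s, e, "+")
        return GenomicInterval(chrom, mirror_at - e, mirror_at - s, "-")

    h1, h2, h3 = iv(100, 200), iv(300, 400), iv(500, 600)
    m1, m2, m3 = (
        iv(100, 200, "mchr1"),
        iv(300, 400, "mchr1"),
        iv(500, 600, "mchr1"),
    )
    human = GeneModel(gene_id=gene_id)
    human.transcripts.append(Transcript(f"{gene_id}.t1", (h1, h2, h3)))
    mouse = GeneModel(gene_id=f"M{gene_id}")
    mouse.transcripts.append(Transcript(f"M{gene_id}.t1", (m1, m2, m3)))

    corr = {
        (h1.start, h1.end): (m1.start, m1.end),
        (h2.start, h2.end): (m2.start, m2.end),
        (h3.start, h3.end): (m3.start, m3.end),
    }
    alu_keys: set[tuple[int, int]] = set()
    if extension:
        d1 = iv(700, 760)
        ext_exons = [h1, h2, h3, d1]
        if alu_flagged:
            alu_keys.add((d1.start, d1.end))
        if post_conserved:
            d2 = iv(900, 960)
            m4 = iv(700, 760, "mchr1")
            ext_exons.append(d2)
            corr[(d2.start, d2.end)] = (m4.start, m4.end)
            mouse.transcripts.append(Transcript(f"M{gene_id}.t2", (m1, m2, m3, m4)))
        human.transcripts.append(Transcript(f"{gene_id}.t2", tuple(ext_exons)))
    elif alu_flagged:
        alu_keys.add((h2.start, h2.end))

    return OrthologPair(
        human_gene=human,
        mouse_gene=mouse,
        exon_correspondence=corr,
        mouse_terminal_in_human=h3,
        alu_exon_keys=frozenset(alu_keys),
    )


# ---------------------------------------------------------------------------
# truth table


def truth_frame(events: Sequence[PlantedEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "gene_id": ev.gene_id,
                "scenario": ev.scenario,
                "alu_exon_chrom": ev.alu_exon.chrom if ev.alu_exon else "",
                "alu_exon_start": ev.alu_exon.start if ev.alu_exon else "",
                "alu_exon_end": ev.alu_exon.end if ev.alu_exon else "",
                "distance_bp": "" if ev.distance_bp is None else ev.distance_bp,
                "inclusion_control": f"{ev.inclusion_control:.6g}",
                "inclusion_kd": f"{ev.inclusion_kd:.6g}",
                "n_downstream_cryptic_exons": ev.n_downstream_cryptic_exons,
                "cryptic_donor": "" if ev.cryptic_donor is None else ev.cryptic_donor,
                "novel_polya": "" if ev.novel_polya is None else ev.novel_polya,
            }
        )
    return pd.DataFrame(rows)
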