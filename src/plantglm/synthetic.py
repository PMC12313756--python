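"""Synthetic data generators with exact truth tables.

These emulate the record geometries of the plant genomic benchmark tasks
and a reference genome with annotated splice junctions, so the whole
pipeline — tokenization, corpus building, dataset construction, model
training and evaluation — is testable at desk scale without any download.

Generators plant clean, fixed-offset motifs (canonical GT/AG intron ends,
a donor/acceptor consensus, an AATAAA-like polyadenylation signal) on an
i.i.d. nucleotide background with configurable GC content; each generator
is bit-reproducible given its seed and returns or stores the ground truth
it planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .junctions import JunctionRecord

__all__ = [
    "SyntheticGenomeSpec",
    "BenchmarkRecord",
    "generate_genome_with_junctions",
    "make_pmb_splice_records",
    "make_apa_records",
    "make_strength_records",
    "DONOR_CONSENSUS",
    "ACCEPTOR_CONSENSUS",
    "APA_SIGNAL",
    "APA_SITE_POS_1BASED",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

# splice-boundary consensus 9-mers; the GT / AG dinucleotide is flanked by
# the strongest consensus positions so a simple scan can find it exactly
DONOR_CONSENSUS = "CAGGTAAGT"     # exon|GTaagt, boundary after offset 3
ACCEPTOR_CONSENSUS = "TTTGCAGGT"  # tttgcAG|exon, boundary after offset 7
APA_SIGNAL = "AATAAA"
APA_SITE_POS_1BASED = 301  # polyadenylation site position in apa400 records


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of the planted-intron genome generator."""

    n_chroms: int = 5
    chrom_length_bp: int = 30_000
    gc_fraction: float = 0.36  # Arabidopsis-like background
    n_introns: int = 40        # per chromosome
    intron_length_range: tuple[int, int] = (60, 200)
    minus_strand_fraction: float = 0.0
    edge_margin_bp: int = 200  # keep junctions clear of contig ends
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intron_length_range[0] < 4:
            raise ValueError("introns need at least 4 bp for GT..AG")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass(frozen=True)
class BenchmarkRecord:
    """One labelled benchmark record (classification or regression)."""

    sequence: str
    label: float | int
    task: str
    meta: tuple[tuple[str, object], ...] = ()

    @property
    def metadata(self) -> dict[str, object]:
        return dict(self.meta)


def generate_genome_with_junctions(
    spec: SyntheticGenomeSpec = SyntheticGenomeSpec(),
) -> tuple[dict[str, str], list[JunctionRecord]]:
    """Generate chromosomes with non-overlapping planted GT..AG introns.

    Chromosome names are ``chr1..chrN``.  Each intron overwrites its first
    two bases with GT and its last two with AG (reversed to CT..AC when
    planted on the minus strand), and surrounding consensus context is
    written so that donor/acceptor windows carry a learnable signal.
    Returns the genome and the truth junction table in the package's
    0-based convention.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    truth: list[JunctionRecord] = []
    lo, hi = spec.intron_length_range
    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        codes = _random_bases(rng, spec.chrom_length_bp, spec.gc_fraction)
        placed: list[tuple[int, int]] = []  # intron intervals incl. 4bp context pad
        attempts = 0
        while len(placed) < spec.n_introns:
            attempts += 1
            if attempts > 200 * spec.n_introns:
                raise RuntimeError(
                    "could not place requested introns without overlap; "
                    "increase chrom_length_bp or reduce n_introns"
                )
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(
                spec.edge_margin_bp,
                spec.chrom_length_bp - spec.edge_margin_bp - length,
            ))
            end = start + length  # half-open intron interval
            if any(start - 10 < e and s < end + 10 for s, e in placed):
                continue
            placed.append((start, end))
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            _plant_intron(codes, start, end, strand)
            truth.append(
                JunctionRecord(
                    chrom=chrom,
                    donor_pos=start,
                    acceptor_pos=end - 1,
                    strand=strand,
                    unique_reads=int(rng.integers(5, 200)),
                )
            )
        genome[chrom] = _to_str(codes)
    truth.sort()
    return genome, truth


_CODE = {b: i for i, b in enumerate("ACGT")}


def _write_motif(codes: np.ndarray, start: int, motif: str) -> None:
    codes[start : start + len(motif)] = [_CODE[b] for b in motif]


def _plant_intron(codes: np.ndarray, start: int, end: int, strand: str) -> None:
    """Overwrite intron boundaries (plus 2-3 bp exonic context) with consensus.

    Plus strand: genome[start-3:start+6] = donor consensus (GT at the first
    two intronic bases) and genome[end-7:end+2] = acceptor consensus (AG at
    the last two).  Minus strand: the biological donor sits at the genomic
    right end and the motifs are planted reverse-complemented, so the
    intron reads CT..AC on the forward strand.
    """
    from .io import reverse_complement

    if strand == "+":
        _write_motif(codes, start - 3, DONOR_CONSENSUS)
        _write_motif(codes, end - 7, ACCEPTOR_CONSENSUS)
    else:
        _write_motif(codes, end - 6, reverse_complement(DONOR_CONSENSUS))
        _write_motif(codes, start - 2, reverse_complement(ACCEPTOR_CONSENSUS))


def make_pmb_splice_records(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    gc_fraction: float = 0.36,
) -> list[BenchmarkRecord]:
    """398 bp binary splice-site records.

    Positives carry the donor or acceptor consensus (chosen alternately)
    planted so the splice boundary falls at the window center (between
    0-based offsets 198 and 199); negatives are plain background with any
    accidental exact consensus at that offset resampled away.  Labels are
    1 (site) / 0 (no site); the class ratio is whatever the caller asks
    for, emulating the strong imbalance of the source data.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("record counts must be non-negative")
    rng = np.random.default_rng(seed)
    length, center = 398, 199
    records: list[BenchmarkRecord] = []
    for i in range(n_pos):
        codes = _random_bases(rng, length, gc_fraction)
        if i % 2 == 0:
            site_kind = "donor"
            _write_motif(codes, center - 3, DONOR_CONSENSUS)
        else:
            site_kind = "acceptor"
            _write_motif(codes, center - 7, ACCEPTOR_CONSENSUS)
        records.append(
            BenchmarkRecord(
                sequence=_to_str(codes), label=1, task="splice398",
                meta=(("site_kind", site_kind), ("boundary_offset", center)),
            )
        )
    donor_win = DONOR_CONSENSUS
    acc_win = ACCEPTOR_CONSENSUS
    for _ in range(n_neg):
        while True:
            codes = _random_bases(rng, length, gc_fraction)
            seq = _to_str(codes)
            if (seq[center - 3 : center - 3 + 9] != donor_win
                    and seq[center - 7 : center - 7 + 9] != acc_win):
                break
        records.append(BenchmarkRecord(sequence=seq, label=0, task="splice398"))
    return records


def make_apa_records(
    n_pos: int,
    shift_bp: int,
    seed: int = 0,
    gc_fraction: float = 0.36,
) -> list[BenchmarkRecord]:
    """400 bp alternative-polyadenylation records.

    Positives place the cleavage site at 1-based position 301 with an
    AATAAA signal 25 bp upstream; each negative reuses the same underlying
    sequence frame shifted by ``shift_bp``, so the site no longer sits at
    position 301.  One negative per positive.
    """
    if not 1 <= shift_bp <= 99:
        raise ValueError("shift_bp must be in [1, 99] so shifted sites stay in range")
    if n_pos < 0:
        raise ValueError("n_pos must be non-negative")
    rng = np.random.default_rng(seed)
    length = 400
    site0 = APA_SITE_POS_1BASED - 1  # 0-based 300
    signal_offset = site0 - 25 - len(APA_SIGNAL)  # AATAAA ends 25 bp before the site
    records: list[BenchmarkRecord] = []
    for _ in range(n_pos):
        mother = _random_bases(rng, length + shift_bp, gc_fraction)
        # positive frame: mother[shift_bp:]; plant the signal inside it
        pos_codes = mother[shift_bp:].copy()
        _write_motif(pos_codes, signal_offset, APA_SIGNAL)
        mother[shift_bp:] = pos_codes
        neg_codes = mother[:length]  # same content, site shifted right by shift_bp
        records.append(
            BenchmarkRecord(
                sequence=_to_str(pos_codes), label=1, task="apa400",
                meta=(("site_pos_1based", APA_SITE_POS_1BASED),
                      ("signal_offset", signal_offset)),
            )
        )
        records.append(
            BenchmarkRecord(
                sequence=_to_str(neg_codes), label=0, task="apa400",
                meta=(("site_pos_1based", APA_SITE_POS_1BASED + shift_bp),
                      ("signal_offset", signal_offset + shift_bp)),
            )
        )
    return records


def make_strength_records(
    n: int,
    motif_weights: Mapping[str, float],
    noise_sd: float = 0.1,
    geometry: str = "promoter",
    seed: int = 0,
    gc_fraction: float = 0.42,
) -> tuple[list[BenchmarkRecord], dict[str, object]]:
    """170 bp regulatory-strength regression records.

    Strength = sum over motifs of weight * (occurrence count in the
    sequence) + Gaussian(0, noise_sd) noise; occurrence counts include
    overlapping matches.  ``geometry`` records what the window emulates:
    ``promoter`` (-165..+5 around a nominal TSS) or ``terminator``
    (-150..+20 around a nominal cleavage site).  Returns the records and a
    truth dict holding the weights and noise-free design matrix.
    """
    if not motif_weights:
        raise ValueError("motif_weights must not be empty")
    if geometry not in ("promoter", "terminator"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for m in motif_weights:
        if not 0 < len(m) < 170:
            raise ValueError(f"motif {m!r} must be shorter than the 170 bp record")
    rng = np.random.default_rng(seed)
    length = 170
    coords = (-165, 5) if geometry == "promoter" else (-150, 20)
    motifs = list(motif_weights)
    records: list[BenchmarkRecord] = []
    design = np.zeros((n, len(motifs)), dtype=float)
    for i in range(n):
        seq = _to_str(_random_bases(rng, length, gc_fraction))
        counts = [_count_overlapping(seq, m) for m in motifs]
        design[i] = counts
        strength = float(
            sum(w * c for w, c in zip(motif_weights.values(), counts))
            + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        )
        records.append(
            BenchmarkRecord(
                sequence=seq, label=strength, task="strength170",
                meta=(("geometry", geometry), ("coords", coords)),
            )
        )
    truth = {
        "motif_weights": dict(motif_weights),
        "noise_sd": noise_sd,
        "geometry": geometry,
        "design_matrix": design,
        "motifs": motifs,
    }
    return records, truth


def _count_overlapping(seq: str, motif: str) -> int:
    count, start = 0, 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def write_records_tsv(records: Sequence[BenchmarkRecord], path: str | Path) -> None:
    """Write records as TSV (sequence, label) with the task name in a header."""
    with open(path, "w") as fh:
        fh.write("sequence\tlabel\n")
        for r in records:
            fh.write(f"{r.sequence}\t{r.label}\n")
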