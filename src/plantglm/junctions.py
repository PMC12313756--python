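"""RNA-seq splice-site dataset construction.

Pipeline: parse splice junctions from aligner output (STAR ``SJ.out.tab``
or BED6), merge near-duplicate junctions whose donor and acceptor
coordinates each differ by at most a tolerance (default +/- 2 bp), extract
fixed-width windows around each donor and acceptor site (default 160 bp:
80 bp upstream and 80 bp downstream of the splice boundary), sample
non-junction negative windows at roughly twice the positive count, and
partition the labelled windows by chromosome (chr1-3 train, chr4
validation, everything else test).

Coordinate conventions
----------------------
Internally everything is 0-based.  ``donor_pos`` is the first intronic
base and ``acceptor_pos`` the last intronic base, so for a canonical
plus-strand intron the genome reads ``GT`` at ``donor_pos..donor_pos+1``
and ``AG`` at ``acceptor_pos-1..acceptor_pos``.  A donor window starts at
``donor_pos - flank`` (the exon|intron boundary falls between window
offsets 79 and 80, so the GT occupies window offsets 80-81); an acceptor
window starts at ``acceptor_pos + 1 - flank`` (AG at offsets 78-79).
Minus-strand windows are reverse-complemented so the motifs read 5'->3'.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import reverse_complement

__all__ = [
    "JunctionRecord",
    "MergedJunction",
    "LabeledWindow",
    "SplitDataset",
    "read_junctions",
    "merge_junctions",
    "extract_site_windows",
    "sample_negatives",
    "split_by_chromosome",
    "write_dataset",
    "read_dataset",
    "donor_motif_slice",
    "acceptor_motif_slice",
]

logger = logging.getLogger(__name__)

LABELS = ("donor", "acceptor", "negative")


@dataclass(frozen=True, order=True)
class JunctionRecord:
    """One splice junction: the intron interval in 0-based coordinates."""

    chrom: str
    donor_pos: int      # first intronic base
    acceptor_pos: int   # last intronic base
    strand: str = "+"   # '+', '-', or 'unknown'
    unique_reads: int = 0

    def __post_init__(self) -> None:
        if self.donor_pos >= self.acceptor_pos:
            raise ValueError(
                f"donor_pos must precede acceptor_pos "
                f"({self.donor_pos} >= {self.acceptor_pos})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def effective_strand(self) -> str:
        """Unknown-strand junctions are processed as plus strand."""
        return "+" if self.strand == "unknown" else self.strand


@dataclass
class MergedJunction:
    """A cluster of near-identical junctions.

    The representative is the member with maximal read support (ties break
    toward smaller donor, then acceptor coordinate).
    """

    representative: JunctionRecord
    members: tuple[JunctionRecord, ...]
    total_unique_reads: int


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed-length window with a donor/acceptor/negative label."""

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match coordinates")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.label)


@dataclass
class SplitDataset:
    train: list[LabeledWindow]
    validation: list[LabeledWindow]
    test: list[LabeledWindow]

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for name in ("train", "validation", "test"):
            part: list[LabeledWindow] = getattr(self, name)
            out[name] = {
                lab: sum(1 for w in part if w.label == lab) for lab in LABELS
            }
            out[name]["total"] = len(part)
        return out


def donor_motif_slice(flank_bp: int = 80) -> slice:
    """Window slice holding the canonical GT of a donor window."""
    return slice(flank_bp, flank_bp + 2)


def acceptor_motif_slice(flank_bp: int = 80) -> slice:
    """Window slice holding the canonical AG of an acceptor window."""
    return slice(flank_bp - 2, flank_bp)


_STAR_STRAND = {0: "unknown", 1: "+", 2: "-"}


def read_junctions(path: str | Path, dialect: str = "star_sj") -> list[JunctionRecord]:
    """Parse splice junctions from a STAR SJ.out.tab or BED6 file.

    star_sj: 9 tab-separated columns; intron coordinates are 1-based
    inclusive and strand is coded 0 (undefined) / 1 (+) / 2 (-); column 7
    holds the uniquely-mapping read count.  bed: BED6 with the intron as a
    0-based half-open interval and the score column as read support.
    """
    if dialect not in ("star_sj", "bed"):
        raise ValueError(f"unknown junction dialect {dialect!r}")
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "star_sj":
                    if len(fields) < 9:
                        raise ValueError(f"expected 9 columns, got {len(fields)}")
                    chrom = fields[0]
                    start_1based = int(fields[1])
                    end_1based = int(fields[2])
                    strand = _STAR_STRAND[int(fields[3])]
                    unique_reads = int(fields[6])
                    donor_pos = start_1based - 1
                    acceptor_pos = end_1based - 1
                else:
                    if len(fields) < 6:
                        raise ValueError(f"expected 6 columns, got {len(fields)}")
                    chrom = fields[0]
                    donor_pos = int(fields[1])
                    acceptor_pos = int(fields[2]) - 1
                    unique_reads = int(float(fields[4]))
                    strand = fields[5] if fields[5] in ("+", "-") else "unknown"
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            records.append(
                JunctionRecord(chrom, donor_pos, acceptor_pos, strand, unique_reads)
            )
    return records


def merge_junctions(
    junctions: Iterable[JunctionRecord], tolerance_bp: int = 2
) -> list[MergedJunction]:
    """Single-linkage merge of junctions within the coordinate tolerance.

    Two junctions on the same (chrom, effective strand) link iff both
    |donor delta| <= tolerance and |acceptor delta| <= tolerance; clusters
    are the connected components.  The result is independent of input
    order and idempotent, sorted by (chrom, representative donor_pos).
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be non-negative")

    groups: dict[tuple[str, str], list[JunctionRecord]] = {}
    for j in junctions:
        groups.setdefault((j.chrom, j.effective_strand), []).append(j)

    merged: list[MergedJunction] = []
    for group in groups.values():
        group.sort(key=lambda j: (j.donor_pos, j.acceptor_pos, -j.unique_reads))
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        # donor-sorted sweep: any linking pair has donor delta <= tolerance,
        # so comparing each junction with its bounded look-back suffices
        for i, ji in enumerate(group):
            for h in range(i - 1, -1, -1):
                jh = group[h]
                if ji.donor_pos - jh.donor_pos > tolerance_bp:
                    break
                if abs(ji.acceptor_pos - jh.acceptor_pos) <= tolerance_bp:
                    parent[find(i)] = find(h)

        clusters: dict[int, list[JunctionRecord]] = {}
        for i in range(len(group)):
            clusters.setdefault(find(i), []).append(group[i])
        for members in clusters.values():
            rep = max(
                members,
                key=lambda j: (j.unique_reads, -j.donor_pos, -j.acceptor_pos),
            )
            merged.append(
                MergedJunction(
                    representative=rep,
                    members=tuple(sorted(members)),
                    total_unique_reads=sum(j.unique_reads for j in members),
                )
            )
    merged.sort(key=lambda m: (m.representative.chrom, m.representative.donor_pos,
                               m.representative.acceptor_pos))
    return merged


def _window_for_boundary(
    seq: str, chrom: str, boundary: int, strand: str, flank_bp: int, label: str
) -> LabeledWindow | None:
    """Window of 2*flank around a splice boundary (a between-base coordinate)."""
    start, end = boundary - flank_bp, boundary + flank_bp
    if start < 0 or end > len(seq):
        return None
    window = seq[start:end]
    if strand == "-":
        window = reverse_complement(window)
    return LabeledWindow(chrom, start, end, strand, window, label)


def extract_site_windows(
    merged: Sequence[MergedJunction],
    reference: Mapping[str, str],
    flank_bp: int = 80,
) -> list[LabeledWindow]:
    """Extract one donor and one acceptor window per merged junction.

    The splice boundary sits between window offsets ``flank-1`` and
    ``flank``.  On the minus strand the biological donor lies at the
    genomic right end of the intron and windows are reverse-complemented.
    Junctions too close to a contig edge are skipped with a warning.
    """
    windows: list[LabeledWindow] = []
    skipped = 0
    for m in merged:
        rep = m.representative
        if rep.chrom not in reference:
            raise KeyError(f"chromosome {rep.chrom!r} absent from reference")
        seq = reference[rep.chrom]
        strand = rep.effective_strand
        if strand == "+":
            boundaries = [(rep.donor_pos, "donor"), (rep.acceptor_pos + 1, "acceptor")]
        else:
            boundaries = [(rep.acceptor_pos + 1, "donor"), (rep.donor_pos, "acceptor")]
        for boundary, label in boundaries:
            w = _window_for_boundary(seq, rep.chrom, boundary, strand, flank_bp, label)
            if w is None:
                skipped += 1
            else:
                windows.append(w)
    if skipped:
        logger.warning("skipped %d windows too close to a contig edge", skipped)
    return windows


def sample_negatives(
    reference: Mapping[str, str],
    junctions: Sequence[MergedJunction],
    ratio: float = 2.0,
    window_bp: int = 160,
    rng: np.random.Generator | None = None,
    n_positive_windows: int | None = None,
) -> list[LabeledWindow]:
    """Sample negative windows that avoid every junction site position.

    The count is ``round(ratio * n_positive_windows)`` (two positive
    windows per merged junction by default).  Placement is uniform over
    valid starts with rejection of windows that intersect any donor or
    acceptor position or contain N.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator is required")
    if n_positive_windows is None:
        n_positive_windows = 2 * len(junctions)
    target = int(round(ratio * n_positive_windows))
    if target == 0:
        return []

    site_lists: dict[str, list[int]] = {c: [] for c in reference}
    for m in junctions:
        rep = m.representative
        site_lists.setdefault(rep.chrom, []).extend([rep.donor_pos, rep.acceptor_pos])
    site_arrays = {c: np.array(sorted(v), dtype=np.int64) for c, v in site_lists.items()}

    chroms = [c for c, s in reference.items() if len(s) >= window_bp]
    if not chroms:
        raise ValueError("reference has no record long enough for a window")
    lengths = np.array([len(reference[c]) - window_bp + 1 for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    negatives: list[LabeledWindow] = []
    seen: set[tuple[str, int]] = set()
    attempts, max_attempts = 0, max(10_000, 200 * target)
    while len(negatives) < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "negative sampling rejection rate too high; "
                "use a larger reference or fewer negatives"
            )
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        start = int(rng.integers(0, len(reference[chrom]) - window_bp + 1))
        end = start + window_bp
        arr = site_arrays.get(chrom)
        if arr is not None and arr.size:
            lo = np.searchsorted(arr, start, side="left")
            if lo < arr.size and arr[lo] < end:
                continue
        window = reference[chrom][start:end]
        if "N" in window:
            continue
        if (chrom, start) in seen:
            continue
        seen.add((chrom, start))
        negatives.append(LabeledWindow(chrom, start, end, "+", window, "negative"))
    return negatives


def _chrom_number(chrom: str) -> str:
    """Normalize 'chr1'/'Chr1'/'1' to '1'; non-numeric names pass through."""
    name = chrom
    for prefix in ("chr", "Chr", "CHR"):
        if name.startswith(prefix):
            name = name[len(prefix):]
            break
    return name


def split_by_chromosome(
    windows: Iterable[LabeledWindow],
    train_chroms: Sequence[str] = ("1", "2", "3"),
    val_chroms: Sequence[str] = ("4",),
    test_rule: str = "rest",
    strict: bool = False,
) -> SplitDataset:
    """Partition windows by chromosome (default: chr1-3 / chr4 / rest).

    Windows are deduplicated on (chrom, start, end, label).  With
    ``strict`` and an explicit test set, a chromosome matching no rule
    raises instead of landing in test.
    """
    train_set = {_chrom_number(c) for c in train_chroms}
    val_set = {_chrom_number(c) for c in val_chroms}
    ds = SplitDataset(train=[], validation=[], test=[])
    seen: set[tuple[str, int, int, str]] = set()
    for w in windows:
        if w.key in seen:
            continue
        seen.add(w.key)
        num = _chrom_number(w.chrom)
        if num in train_set:
            ds.train.append(w)
        elif num in val_set:
            ds.validation.append(w)
        elif test_rule == "rest":
            ds.test.append(w)
        elif strict:
            raise ValueError(f"chromosome {w.chrom!r} matches no partition rule")
        else:
            ds.test.append(w)
    for name, part_counts in ds.counts().items():
        logger.info("split %s: %s", name, part_counts)
    return ds


_TSV_COLUMNS = ["chrom", "start", "end", "strand", "label", "sequence"]


def write_dataset(
    ds: SplitDataset,
    out_dir: str | Path,
    config: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> dict[str, object]:
    """Write train/validation/test TSVs plus a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name in ("train", "validation", "test"):
        part: list[LabeledWindow] = getattr(ds, name)
        df = pd.DataFrame(
            [(w.chrom, w.start, w.end, w.strand, w.label, w.sequence) for w in part],
            columns=_TSV_COLUMNS,
        )
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        files[name] = path.name
    manifest: dict[str, object] = {
        "files": files,
        "counts": ds.counts(),
        "config": dict(config) if config else {},
        "seed": seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_dataset(out_dir: str | Path) -> SplitDataset:
    """Re-read a dataset written by :func:`write_dataset`."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    parts: dict[str, list[LabeledWindow]] = {}
    for name, fname in manifest["files"].items():
        df = pd.read_csv(out_dir / fname, sep="\t", dtype={"chrom": str})
        parts[name] = [
            LabeledWindow(
                str(r.chrom), int(r.start), int(r.end), str(r.strand),
                str(r.sequence), str(r.label),
            )
            for r in df.itertuples(index=False)
        ]
    return SplitDataset(
        train=parts.get("train", []),
        validation=parts.get("validation", []),
        test=parts.get("test", []),
    )
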