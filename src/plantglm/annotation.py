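"""Sliding-window genome annotation inference.

A fine-tuned 3-class splice model is slid across a genomic region; each
window is classified and its donor/acceptor/negative logits are assigned
to the window's splice-boundary coordinate (window start + flank, i.e.
start + 80 for the default 160 bp window), matching how positive training
windows were centered.  Tracks are written as one bedGraph per class plus
a raw TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model.encoder import TaskModel, predict_logits
from .tokenization import TokenizerSpec

__all__ = ["ScanConfig", "LogitTrack", "scan_region", "write_tracks", "read_track_tsv"]

CLASS_NAMES = ("donor", "acceptor", "negative")


@dataclass(frozen=True)
class ScanConfig:
    """Region and tiling parameters for annotation inference."""

    region: tuple[str, int, int]  # (chrom, start, end), 0-based half-open
    window_bp: int = 160
    stride_bp: int = 1

    def __post_init__(self) -> None:
        if self.stride_bp < 1:
            raise ValueError("stride_bp must be >= 1")
        chrom, start, end = self.region
        if end - start < self.window_bp:
            raise ValueError("region shorter than the scanning window")


@dataclass
class LogitTrack:
    """Per-window class logits keyed by splice-boundary coordinate."""

    chrom: str
    centers: np.ndarray           # strictly increasing by stride
    logits: np.ndarray            # (n_windows, 3) in CLASS_NAMES order
    window_bp: int
    stride_bp: int

    def __len__(self) -> int:
        return len(self.centers)

    def argmax_position(self, class_name: str) -> int:
        """Coordinate with the highest logit for a class."""
        ci = CLASS_NAMES.index(class_name)
        return int(self.centers[int(np.argmax(self.logits[:, ci]))])


def scan_region(
    model: TaskModel,
    tokenizer: TokenizerSpec,
    reference: Mapping[str, str],
    config: ScanConfig,
    batch_size: int = 64,
) -> LogitTrack:
    """Classify every window tiling the region and collect logit tracks.

    Windows start at ``start, start + stride, ...`` while they fit inside
    the region; each window's logits are assigned to its boundary
    coordinate ``window_start + window_bp // 2``.
    """
    chrom, start, end = config.region
    if chrom not in reference:
        raise KeyError(f"chromosome {chrom!r} absent from reference")
    seq = reference[chrom]
    if end > len(seq):
        raise ValueError("region extends past the end of the chromosome")
    if model.n_classes != 3:
        raise ValueError("scan_region expects a 3-class splice model")

    starts = np.arange(start, end - config.window_bp + 1, config.stride_bp)
    windows = [seq[s : s + config.window_bp] for s in starts]
    logits = predict_logits(model, windows, batch_size=batch_size)
    centers = starts + config.window_bp // 2
    return LogitTrack(
        chrom=chrom,
        centers=centers,
        logits=np.asarray(logits),
        window_bp=config.window_bp,
        stride_bp=config.stride_bp,
    )


def write_tracks(track: LogitTrack, out_prefix: str | Path) -> dict[str, str]:
    """Write one bedGraph per class plus a raw TSV; returns the manifest.

    bedGraph intervals are 0-based half-open of width = stride, sorted and
    non-overlapping.
    """
    if len(track) == 0:
        raise ValueError("cannot write an empty track")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for ci, name in enumerate(CLASS_NAMES):
        path = out_prefix.parent / f"{out_prefix.name}.{name}.bedgraph"
        with open(path, "w") as fh:
            for center, value in zip(track.centers, track.logits[:, ci]):
                fh.write(
                    f"{track.chrom}\t{center}\t{center + track.stride_bp}\t{value:.6g}\n"
                )
        manifest[name] = str(path)
    tsv = out_prefix.parent / f"{out_prefix.name}.logits.tsv"
    df = pd.DataFrame(
        {
            "chrom": track.chrom,
            "center": track.centers,
            "donor_logit": track.logits[:, 0],
            "acceptor_logit": track.logits[:, 1],
            "negative_logit": track.logits[:, 2],
        }
    )
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    manifest["tsv"] = str(tsv)
    return manifest


def read_track_tsv(path: str | Path, window_bp: int = 160, stride_bp: int | None = None) -> LogitTrack:
    """Re-read a raw TSV written by :func:`write_tracks`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    centers = df["center"].to_numpy()
    if stride_bp is None:
        stride_bp = int(centers[1] - centers[0]) if len(centers) > 1 else 1
    logits = df[["donor_logit", "acceptor_logit", "negative_logit"]].to_numpy()
    return LogitTrack(
        chrom=str(df["chrom"].iloc[0]),
        centers=centers,
        logits=logits,
        window_bp=window_bp,
        stride_bp=stride_bp,
    )
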