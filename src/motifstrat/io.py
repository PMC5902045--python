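"""Readers and writers for the package's on-disk formats.

Formats: FASTA (sequences), JASPAR PFM (count matrices), MEME minimal
(probability matrices), BED4+/narrowPeak (ChIP peaks), plain-text pools
(one uppercase sequence per line, B1H "Unique Raw Sequence" dialect),
and TSV tables for PBM probes and EMSA titrations.  Base order is
normalised to A,C,G,T everywhere; coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .motif import PCM, PWM, BASES
from .evaluate import ChIPPeak, PBMProbe

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_motif",
    "write_jaspar",
    "write_meme",
    "read_peaks",
    "read_pool",
    "write_pool",
    "read_pbm_table",
    "write_pbm_table",
    "read_emsa_table",
    "write_emsa_table",
    "write_bed",
]

_VALID = set("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """FASTA records as an ordered id -> uppercase-sequence mapping.

    Rejects duplicate ids, empty records, and any letter outside ACGTN
    (naming the record and offset).
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        for i, ch in enumerate(seq):
            if ch not in _VALID:
                raise ValueError(
                    f"record {rec.id!r}: invalid base {ch!r} at offset {i}"
                )
        records[rec.id] = seq
    return records


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_motif(path, fmt: str = "auto"):
    """Read a JASPAR PFM (-> :class:`PCM`) or MEME minimal (-> :class:`PWM`).

    ``fmt="auto"`` sniffs: files starting with "MEME version" are MEME
    minimal, otherwise JASPAR.  MEME probability rows that sum to 1
    within 1e-3 are renormalised with a warning; larger deviations are
    errors with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    if fmt == "auto":
        fmt = "meme" if text.lstrip().startswith("MEME") else "jaspar"
    if fmt == "jaspar":
        return _read_jaspar(path, text)
    if fmt == "meme":
        return _read_meme(path, text)
    raise ValueError(f"unknown motif format {fmt!r}")


def _read_jaspar(path: Path, text: str) -> PCM:
    with open(path) as fh:
        try:
            m = bio_motifs.read(fh, "jaspar")
        except Exception as exc:
            raise ValueError(f"{path}: not a valid JASPAR PFM ({exc})") from exc
    cols = len(m.counts["A"])
    counts = np.array([[m.counts[b][i] for b in BASES] for i in range(cols)])
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative counts in JASPAR matrix")
    if np.any(counts != np.round(counts)):
        warnings.warn(f"{path}: non-integer JASPAR counts, rounding", stacklevel=2)
    return PCM(np.round(counts).astype(int), name=m.name or path.stem)


def _read_meme(path: Path, text: str) -> PWM:
    lines = text.splitlines()
    name = None
    rows: list[list[float]] = []
    width = None
    in_matrix = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("MOTIF"):
            name = stripped.split(None, 2)[1] if len(stripped.split()) > 1 else "motif"
            in_matrix = False
        elif stripped.startswith("letter-probability matrix"):
            in_matrix = True
            toks = stripped.replace("=", " ").split()
            for i, t in enumerate(toks):
                if t == "w" and i + 1 < len(toks):
                    width = int(toks[i + 1])
        elif in_matrix and stripped:
            vals = stripped.split()
            if len(vals) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 probabilities, got {len(vals)}"
                )
            try:
                row = [float(v) for v in vals]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric probability") from None
            total = sum(row)
            if abs(total - 1.0) > 1e-3 * (1 + 1e-6):
                raise ValueError(
                    f"{path}:{lineno}: probabilities sum to {total:.6f}, not 1"
                )
            if abs(total - 1.0) > 1e-4:
                warnings.warn(
                    f"{path}:{lineno}: probabilities sum to {total:.6f}; "
                    "renormalising",
                    stacklevel=3,
                )
            rows.append([v / total for v in row])
        elif in_matrix and not stripped:
            in_matrix = False
    if not rows:
        raise ValueError(f"{path}: no letter-probability matrix found")
    if width is not None and width != len(rows):
        raise ValueError(
            f"{path}: header width {width} != {len(rows)} matrix rows"
        )
    probs = np.clip(np.asarray(rows), 1e-9, None)
    return PWM(probs / probs.sum(axis=1, keepdims=True), name=name or path.stem)


def write_jaspar(path, pcm: PCM) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pcm.name}\n")
        for bi, b in enumerate(BASES):
            vals = " ".join(f"{int(c):6d}" for c in pcm.counts[:, bi])
            fh.write(f"{b} [{vals} ]\n")


def write_meme(path, pwms, background=None) -> None:
    """MEME minimal motif file with one or more letter-probability blocks."""
    if isinstance(pwms, PWM):
        pwms = [pwms]
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {q:.5f}" for b, q in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_peaks(path, fe_column: int = 6) -> list[ChIPPeak]:
    """BED4+/narrowPeak peaks with fold enrichment.

    ``fe_column`` is the 0-based column index of the fold-enrichment
    value (6 = narrowPeak signalValue).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) <= fe_column:
                raise ValueError(
                    f"{path}:{lineno}: only {len(parts)} columns, need the "
                    f"fold-enrichment column at index {fe_column}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
            try:
                fe = float(parts[fe_column])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric fold enrichment "
                    f"{parts[fe_column]!r}"
                ) from None
            name = parts[3] if len(parts) > 3 else f"peak{lineno}"
            try:
                peaks.append(ChIPPeak(parts[0], start, end, fe, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_bed(path, intervals) -> None:
    """(chrom, start, end[, ...]) tuples or ChIPPeak objects to BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, ChIPPeak):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t.\t"
                    f"{iv.fold_enrichment:.4f}\n"
                )
            else:
                fh.write("\t".join(str(x) for x in iv) + "\n")


def read_pool(path) -> list[str]:
    """Plain-text pool: one sequence per line; optional second column
    (a count) accepted and ignored; blank lines skipped."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            seq = parts[0].upper()
            if set(seq) - set("ACGT"):
                raise ValueError(
                    f"{path}:{lineno}: sequence contains non-ACGT letters"
                )
            hits.append(seq)
    return hits


def write_pool(path, sequences) -> None:
    Path(path).write_text("".join(s + "\n" for s in sequences))


def read_pbm_table(path) -> list[PBMProbe]:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "sequence", "fluorescence"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    lengths = df["sequence"].str.len().unique()
    if lengths.size > 1:
        raise ValueError(f"{path}: probe sequences must have uniform length")
    return [
        PBMProbe(r.probe_id, r.sequence.upper(), float(r.fluorescence))
        for r in df.itertuples()
    ]


def write_pbm_table(path, probes) -> None:
    if isinstance(probes, pd.DataFrame):
        probes.to_csv(path, sep="\t", index=False)
        return
    pd.DataFrame(
        [(p.probe_id, p.sequence, p.fluorescence) for p in probes],
        columns=["probe_id", "sequence", "fluorescence"],
    ).to_csv(path, sep="\t", index=False)


def read_emsa_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "proportion_bound" not in df.columns:
        raise ValueError(f"{path}: need a 'proportion_bound' column")
    if not ({"E", "sequence"} & set(df.columns)):
        raise ValueError(f"{path}: need an 'E' or 'sequence' column")
    return df


def write_emsa_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
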