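"""Decode sequencing reads into a CodeA x CodeB count matrix.

Code slots are located by fixed offsets from the read start (the simulator
writes a constant-layout read; adapter scanning is out of scope).  Each slot
is matched against its codebook with up to ``max_mismatch`` substitutions;
because the codebooks guarantee a minimum pairwise Hamming distance d_min,
any read with at most ``floor((d_min - 1) / 2)`` substitutions per slot
decodes uniquely.  Reads whose best match ties between two codes are
discarded as ambiguous rather than arbitrarily assigned, so decoding errors
deflate counts but never systematically misassign them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import CodeOligo, DesignManifest, hamming
from .simulate import DEFAULT_LAYOUT, ReadLayout

logger = logging.getLogger("deldeck")

#: sentinel returned when >= 2 codes tie at the minimum qualifying distance
AMBIGUOUS = "__ambiguous__"

DISCARD_REASONS = ("no-match-A", "no-match-B", "ambiguous")


class DecodeConfigError(ValueError):
    """Raised when decode parameters break the unique-correction guarantee."""


def match_code(
    observed: str, codebook: Sequence[CodeOligo], max_mismatch: int, d_min: Optional[int] = None
) -> Optional[str]:
    """Match one observed slot against a codebook.

    Returns the code_id of the unique code within Hamming distance
    ``max_mismatch``; :data:`AMBIGUOUS` if two or more codes tie at the
    minimum qualifying distance; ``None`` if no code qualifies.  If ``d_min``
    is given, ``max_mismatch >= d_min`` is rejected because correction is no
    longer unique in the worst case.
    """
    if d_min is not None and max_mismatch >= d_min:
        raise DecodeConfigError(
            f"max_mismatch={max_mismatch} >= d_min={d_min}: correction not unique"
        )
    if len(observed) != len(codebook[0].sequence):
        raise ValueError(
            f"observed slot length {len(observed)} != code length {len(codebook[0].sequence)}"
        )
    best_d, best_ids = max_mismatch + 1, []
    for code in codebook:
        d = hamming(observed, code.sequence)
        if d < best_d:
            best_d, best_ids = d, [code.code_id]
        elif d == best_d:
            best_ids.append(code.code_id)
    if best_d > max_mismatch:
        return None
    return best_ids[0] if len(best_ids) == 1 else AMBIGUOUS


@dataclass
class CountMatrix:
    """Decoded reads aggregated on the CodeA x CodeB grid.

    ``tcs`` (total sequence counts) is the grid sum; ``acs`` (average
    sequence counts) is tcs divided by the grid size, kept exact as a
    Fraction until display.
    """

    counts: np.ndarray  # shape (|A|, |B|), integer
    a_ids: list[str]
    b_ids: list[str]
    discarded: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in DISCARD_REASONS}
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.a_ids), len(self.b_ids)):
            raise ValueError("counts shape does not match code id lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def tcs(self) -> int:
        return int(self.counts.sum())

    @property
    def grid_size(self) -> int:
        return len(self.a_ids) * len(self.b_ids)

    @property
    def acs(self) -> Fraction:
        """Exact average sequence counts: tcs / (|A| * |B|)."""
        return Fraction(self.tcs, self.grid_size)

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    @property
    def reads_processed(self) -> int:
        return self.tcs + self.n_discarded

    # -- I/O -------------------------------------------------------------

    def to_frame(self, drop_zero: bool = False) -> pd.DataFrame:
        ai, bi = np.meshgrid(np.arange(len(self.a_ids)), np.arange(len(self.b_ids)), indexing="ij")
        df = pd.DataFrame(
            {
                "code_a": np.asarray(self.a_ids, dtype=object)[ai.ravel()],
                "code_b": np.asarray(self.b_ids, dtype=object)[bi.ravel()],
                "count": self.counts.ravel(),
            }
        )
        return df[df["count"] > 0].reset_index(drop=True) if drop_zero else df

    def to_tsv(self, path: str | Path, drop_zero: bool = True) -> None:
        self.to_frame(drop_zero=drop_zero).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, a_ids: Sequence[str], b_ids: Sequence[str]
    ) -> "CountMatrix":
        a_pos = {a: i for i, a in enumerate(a_ids)}
        b_pos = {b: i for i, b in enumerate(b_ids)}
        counts = np.zeros((len(a_ids), len(b_ids)), dtype=np.int64)
        for ca, cb, c in zip(df["code_a"], df["code_b"], df["count"]):
            counts[a_pos[str(ca)], b_pos[str(cb)]] += int(c)
        return cls(counts, list(a_ids), list(b_ids))

    @classmethod
    def from_tsv(
        cls, path: str | Path, a_ids: Sequence[str], b_ids: Sequence[str]
    ) -> "CountMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"), a_ids, b_ids)

    @classmethod
    def from_pairs(
        cls, code_a: Sequence[str], code_b: Sequence[str], a_ids, b_ids
    ) -> "CountMatrix":
        """Aggregate per-read (code_a, code_b) assignments, e.g. a truth table."""
        df = (
            pd.DataFrame({"code_a": list(code_a), "code_b": list(code_b)})
            .groupby(["code_a", "code_b"], sort=False)
            .size()
            .reset_index(name="count")
        )
        return cls.from_frame(df, a_ids, b_ids)


def format_acs(acs: Fraction) -> str:
    """Display convention: integers unrounded, else half-up to 2 decimals."""
    if acs.denominator == 1:
        return str(acs.numerator)
    d = Decimal(acs.numerator) / Decimal(acs.denominator)
    return str(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(matrix: CountMatrix) -> dict:
    """TCs, exact and display ACs, and discard fractions for one decoded run."""
    processed = matrix.reads_processed
    return {
        "tcs": matrix.tcs,
        "acs": float(matrix.acs),
        "acs_display": format_acs(matrix.acs),
        "grid_size": matrix.grid_size,
        "reads_processed": processed,
        "discarded": dict(matrix.discarded),
        "discard_fractions": {
            k: (v / processed if processed else 0.0) for k, v in matrix.discarded.items()
        },
    }


# ---------------------------------------------------------------------------
# Bulk decoding
# ---------------------------------------------------------------------------

def _codebook_matrix(codebook: Sequence[CodeOligo]) -> np.ndarray:
    return np.frombuffer(
        "".join(c.sequence for c in codebook).encode(), dtype=np.uint8
    ).reshape(len(codebook), -1)


def _match_slots(
    slots: np.ndarray, codebook: Sequence[CodeOligo], max_mismatch: int
) -> np.ndarray:
    """Vectorised slot matching.

    `slots` is a (n_reads, L) uint8 matrix.  Returns an int array of code
    indices, with -1 for no match and -2 for ambiguous.  Exact matches are
    resolved through a hash lookup; only inexact slots pay for the full
    distance computation against the codebook.
    """
    n, L = slots.shape
    out = np.full(n, -1, dtype=np.int64)
    exact = {c.sequence.encode(): i for i, c in enumerate(codebook)}
    slot_bytes = slots.view(f"S{L}").ravel()
    unresolved = []
    for i, sb in enumerate(slot_bytes):
        hit = exact.get(sb)
        if hit is not None:
            out[i] = hit
        else:
            unresolved.append(i)
    if not unresolved or max_mismatch == 0:
        return out
    idx = np.asarray(unresolved)
    book = _codebook_matrix(codebook)
    for start in range(0, idx.size, 8192):
        chunk = idx[start : start + 8192]
        # (chunk, n_codes) Hamming distances
        dist = (slots[chunk][:, None, :] != book[None, :, :]).sum(axis=2)
        dmin = dist.min(axis=1)
        n_at_min = (dist == dmin[:, None]).sum(axis=1)
        ok = dmin <= max_mismatch
        amb = ok & (n_at_min > 1)
        uniq = ok & (n_at_min == 1)
        out[chunk[uniq]] = dist[uniq].argmin(axis=1)
        out[chunk[amb]] = -2
    return out


def decode_fastq(
    reads_path: str | Path,
    manifest: DesignManifest,
    max_mismatch: int = 1,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> CountMatrix:
    """Decode a FASTQ file into a CountMatrix with discard accounting.

    Every read is assigned to exactly one grid cell or one discard reason
    (no-match-A, no-match-B, ambiguous), so assigned + discarded equals the
    number of reads processed.  Requires ``max_mismatch < d_min`` so that
    correction stays unique.
    """
    if max_mismatch >= manifest.d_min:
        raise DecodeConfigError(
            f"max_mismatch={max_mismatch} >= d_min={manifest.d_min}: correction not unique"
        )
    len_a, len_b = manifest.code_length_a, manifest.code_length_b
    slot_a, slot_b = layout.slots(len_a, len_b)
    min_len = layout.read_length(len_a, len_b)

    seqs: list[str] = []
    with open(reads_path) as fh:
        for rec_idx, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
            if len(seq) < min_len:
                raise ValueError(
                    f"malformed FASTQ record {rec_idx} ({title!r}): read length "
                    f"{len(seq)} < expected {min_len}"
                )
            seqs.append(seq)

    n = len(seqs)
    counts = np.zeros((len(manifest.a_ids), len(manifest.b_ids)), dtype=np.int64)
    matrix = CountMatrix(counts, manifest.a_ids, manifest.b_ids)
    if n == 0:
        return matrix

    read_mat = np.frombuffer(
        "".join(s[:min_len] for s in seqs).encode(), dtype=np.uint8
    ).reshape(n, min_len)
    ia = _match_slots(read_mat[:, slot_a], manifest.codebook_a, max_mismatch)
    ib = _match_slots(read_mat[:, slot_b], manifest.codebook_b, max_mismatch)

    ambiguous = (ia == -2) | (ib == -2)
    no_a = (ia == -1) & ~ambiguous
    no_b = (ib == -1) & ~ambiguous & ~no_a
    assigned = ~(ambiguous | no_a | no_b)
    np.add.at(counts, (ia[assigned], ib[assigned]), 1)
    matrix.discarded["ambiguous"] = int(ambiguous.sum())
    matrix.discarded["no-match-A"] = int(no_a.sum())
    matrix.discarded["no-match-B"] = int(no_b.sum())

    assert matrix.reads_processed == n, "conservation violated: assigned + discarded != reads"
    logger.info(
        "decoded %s: %d reads, %d assigned (TCs), %d discarded",
        reads_path, n, matrix.tcs, matrix.n_discarded,
    )
    return matrix


def write_summary(matrix: CountMatrix, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summarize(matrix), indent=2) + "\n")
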