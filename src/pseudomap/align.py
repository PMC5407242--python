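"""Built-in nucleotide aligner producing BLAST-tabular (outfmt-6-like) HSPs.

The pipeline only ever needs to detect near-identical local alignments
(>= 99% identity) between assemblies of the same genotype, so a light
seed-and-extend strategy suffices: exact k-mer anchors (k=31 by default) are
collected per (subject, strand, diagonal), chained along the diagonal and
extended without gaps. Coordinates follow the BLAST tabular convention:
1-based inclusive, with subject start > subject end on minus-strand hits.

Externally produced 12-column BLAST tables can be ingested with
:func:`read_blast_table` for parity with runs that used a standalone aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BLAST6_COLUMNS = [
    "query",
    "subject",
    "identity",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Hsp:
    """One high-scoring pair between a query and a subject sequence."""

    query: str
    subject: str
    identity: float  # percent
    length: int
    mismatch: int
    qstart: int  # 1-based inclusive
    qend: int
    sstart: int  # sstart > send on minus strand
    send: int

    @property
    def strand(self) -> int:
        return 1 if self.send >= self.sstart else -1

    def query_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the query."""
        return (self.qstart - 1, self.qend)

    def subject_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the subject (strand-normalised)."""
        if self.strand > 0:
            return (self.sstart - 1, self.send)
        return (self.send - 1, self.sstart)


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, packed 2-bit codes) of all valid k-mers."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    acc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        acc = (acc << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return pos, acc[valid]


class KmerIndex:
    """Sorted-array k-mer index over a set of subject sequences.

    K-mers occurring more than ``max_occ`` times are dropped from lookups;
    they stem from high-copy repeats and would only yield spurious anchors.
    """

    def __init__(self, subjects: Mapping[str, str], k: int = 31, max_occ: int = 200):
        self.k = k
        self.names = list(subjects)
        self.lengths = {name: len(s) for name, s in subjects.items()}
        pos_parts, code_parts, sid_parts = [], [], []
        for idx, name in enumerate(self.names):
            pos, codes = _kmer_codes(_encode(subjects[name]), k)
            pos_parts.append(pos)
            code_parts.append(codes)
            sid_parts.append(np.full(pos.size, idx, dtype=np.int32))
        codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.uint64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = (
            np.concatenate(pos_parts)[order] if pos_parts else np.empty(0, np.int64)
        )
        self.sid = (
            np.concatenate(sid_parts)[order] if sid_parts else np.empty(0, np.int32)
        )
        # mask high-occurrence k-mers
        if self.codes.size:
            uniq, counts = np.unique(self.codes, return_counts=True)
            heavy = uniq[counts > max_occ]
            if heavy.size:
                drop = np.isin(self.codes, heavy)
                self.codes = self.codes[~drop]
                self.pos = self.pos[~drop]
                self.sid = self.sid[~drop]

    def lookup(self, qpos: np.ndarray, qcodes: np.ndarray):
        """Anchor arrays (query pos, subject idx, subject pos) for all hits."""
        if self.codes.size == 0 or qcodes.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.int32), e
        lo = np.searchsorted(self.codes, qcodes, side="left")
        hi = np.searchsorted(self.codes, qcodes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.int32), e
        qp = np.repeat(qpos, counts)
        base = np.repeat(lo, counts)
        cum = np.cumsum(counts) - counts
        offsets = base + (np.arange(total) - np.repeat(cum, counts))
        return qp, self.sid[offsets], self.pos[offsets]


def _extend_and_score(
    q: np.ndarray, s: np.ndarray, qs: int, qe: int, diag: int
) -> tuple[int, int, int]:
    """Greedy ungapped extension of query segment [qs, qe) on ``diag``
    (= qpos - spos). Returns (qs, qe, mismatches)."""
    while qs > 0 and qs - diag > 0 and q[qs - 1] == s[qs - 1 - diag] and q[qs - 1] < 4:
        qs -= 1
    n, m = q.size, s.size
    while qe < n and qe - diag < m and q[qe] == s[qe - diag] and q[qe] < 4:
        qe += 1
    seg_q = q[qs:qe]
    seg_s = s[qs - diag : qe - diag]
    mism = int(np.count_nonzero(seg_q != seg_s) + np.count_nonzero(seg_q >= 4))
    return qs, qe, mism


def align_pairwise(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    *,
    k: int = 31,
    min_identity: float = 99.0,
    min_length: int = 500,
    chain_gap: int = 40,
    max_occ: int = 200,
    qstride: int = 4,
    skip_self: bool = True,
    index: "KmerIndex | None" = None,
) -> list[Hsp]:
    """All-vs-all local alignment of ``queries`` against ``subjects``.

    ``skip_self`` drops the trivial identity hit of a sequence against
    itself (the full-length plus-strand diagonal-0 alignment), which is what
    self-alignment screens want ignored.
    """
    if index is None:
        index = KmerIndex(subjects, k=k, max_occ=max_occ)
    subj_codes = {name: _encode(seq) for name, seq in subjects.items()}
    hsps: list[Hsp] = []
    for qname, qseq in queries.items():
        qcodes_fwd = _encode(qseq)
        qlen = len(qseq)
        for strand in (1, -1):
            qarr = qcodes_fwd if strand > 0 else _encode(revcomp(qseq))
            pos, codes = _kmer_codes(qarr, k)
            if qstride > 1:
                pos, codes = pos[::qstride], codes[::qstride]
            qp, sid, sp = index.lookup(pos, codes)
            if qp.size == 0:
                continue
            diag = qp - sp
            # group anchors by (subject, diagonal)
            key = sid.astype(np.int64) * (1 << 33) + (diag + (1 << 32))
            order = np.lexsort((qp, key))
            key, qp, sid, diag = key[order], qp[order], sid[order], diag[order]
            boundaries = np.nonzero(
                (np.diff(key) != 0) | (np.diff(qp) > chain_gap)
            )[0]
            starts = np.concatenate(([0], boundaries + 1))
            ends = np.concatenate((boundaries + 1, [qp.size]))
            for a, b in zip(starts, ends):
                sname = index.names[sid[a]]
                d = int(diag[a])
                qs, qe = int(qp[a]), int(qp[b - 1]) + k
                if skip_self and sname == qname and strand > 0 and d == 0:
                    continue
                sarr = subj_codes[sname]
                qs, qe, mism = _extend_and_score(qarr, sarr, qs, qe, d)
                length = qe - qs
                if length < min_length:
                    continue
                ident = 100.0 * (length - mism) / length
                if ident < min_identity:
                    continue
                ss, se = qs - d, qe - d  # subject coords, 0-based half-open
                if strand > 0:
                    hsps.append(
                        Hsp(qname, sname, round(ident, 2), length, mism,
                            qs + 1, qe, ss + 1, se)
                    )
                else:
                    # anchors were found on revcomp(query): map back
                    rqs, rqe = qlen - qe, qlen - qs
                    hsps.append(
                        Hsp(qname, sname, round(ident, 2), length, mism,
                            rqs + 1, rqe, se, ss + 1)
                    )
    return _dedup(hsps)


def _dedup(hsps: list[Hsp]) -> list[Hsp]:
    """Drop exact duplicates and keep the longest HSP among identical spans
    (chains split by the gap heuristic can re-emit the same region)."""
    seen = set()
    out = []
    for h in sorted(hsps, key=lambda h: (h.query, h.subject, h.qstart, -h.length)):
        key = (h.query, h.subject, h.qstart, h.qend, h.sstart, h.send)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    return out


def hsps_to_frame(hsps: Iterable[Hsp]) -> pd.DataFrame:
    """Serialise HSPs into the 12-column BLAST tabular dialect."""
    rows = [
        (
            h.query, h.subject, h.identity, h.length, h.mismatch, 0,
            h.qstart, h.qend, h.sstart, h.send, 0.0, 2.0 * h.length,
        )
        for h in hsps
    ]
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def frame_to_hsps(df: pd.DataFrame) -> list[Hsp]:
    return [
        Hsp(
            str(r.query), str(r.subject), float(r.identity), int(r.length),
            int(r.mismatch), int(r.qstart), int(r.qend), int(r.sstart),
            int(r.send),
        )
        for r in df.itertuples()
    ]


def read_blast_table(path) -> pd.DataFrame:
    """Read an externally produced 12-column BLAST tabular file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 12:
        raise ValueError(
            f"expected 12 columns in BLAST tabular input, got {df.shape[1]}"
        )
    df.columns = BLAST6_COLUMNS
    return df
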