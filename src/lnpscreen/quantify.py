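"""FASTQ -> deduplicated barcode x sample molecule counts.

Three stages per read: positional extraction against a :class:`ReadLayout`
(with a mismatch-tolerant prefix anchor check), whitelist assignment of the
barcode region (exact match wins, else the unique entry within a Hamming
budget), and per-(sample, barcode) UMI collapse using the directional
adjacency rule: UMI ``v`` is absorbed into a single-base neighbor ``u``
when ``count(u) >= 2*count(v) - 1``.

The per-sample engine is single-pass and batched: reads are streamed with
Biopython's FastqGeneralIterator and processed as numpy byte matrices, so
memory is O(#distinct (barcode, UMI) pairs) plus one batch.
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from lnpscreen.simulate import (
    NAKED_LNP,
    BarcodeWhitelist,
    ReadLayout,
    _BASE_TO_CODE,
)

__all__ = [
    "ASSIGNED",
    "UNMATCHED",
    "AMBIGUOUS",
    "ANCHOR_FAIL",
    "CountTable",
    "extract_barcode_umi",
    "match_whitelist",
    "collapse_umis",
    "build_count_table",
]

ASSIGNED = "assigned"
UNMATCHED = "unmatched_barcode"
AMBIGUOUS = "ambiguous_barcode"
ANCHOR_FAIL = "anchor_fail"

_BATCH_READS = 200_000


def _hamming(a: str, b: str) -> int:
    # N (or any non-matching symbol) counts as a mismatch
    return sum(x != y for x, y in zip(a, b))


def extract_barcode_umi(
    read: str, layout: ReadLayout, anchor_max_mm: int = 2
) -> tuple[str, str] | None:
    """Slice (barcode_seq, umi_seq) at layout coordinates; ``None`` on anchor failure.

    The anchor check compares the observed constant prefix to
    ``layout.prefix_seq`` with at most ``anchor_max_mm`` mismatches.  Reads
    shorter than the layout fail the anchor.
    """
    if len(read) < layout.total_len:
        return None
    if _hamming(read[: layout.prefix_len], layout.prefix_seq) > anchor_max_mm:
        return None
    return read[layout.barcode_slice], read[layout.umi_slice]


class _WhitelistMatcher:
    """Exact + 1-mismatch-neighbor lookup tables over a whitelist."""

    def __init__(self, whitelist: BarcodeWhitelist, max_mm: int):
        self.max_mm = max_mm
        self.ids = whitelist.barcode_ids
        self.seqs = whitelist.sequences
        self.exact = {s: i for i, s in enumerate(self.seqs)}
        if whitelist.min_pairwise_hamming < 2 * max_mm + 1:
            warnings.warn(
                f"whitelist min pairwise distance {whitelist.min_pairwise_hamming} "
                f"< {2 * max_mm + 1}; correction at max_mm={max_mm} may be ambiguous",
                stacklevel=3,
            )
        self.neighbors: dict[str, int] = {}
        if max_mm == 1:
            for i, s in enumerate(self.seqs):
                for pos in range(len(s)):
                    for base in "ACGT":
                        if base == s[pos]:
                            continue
                        nb = s[:pos] + base + s[pos + 1 :]
                        if nb in self.exact:
                            continue  # exact match takes precedence
                        if nb in self.neighbors and self.neighbors[nb] != i:
                            self.neighbors[nb] = -1  # ambiguous
                        else:
                            self.neighbors.setdefault(nb, i)

    def match(self, seq: str) -> tuple[str, str | None]:
        """Return (status, barcode_id-or-None)."""
        idx = self.exact.get(seq)
        if idx is not None:
            return ASSIGNED, self.ids[idx]
        if self.max_mm == 0:
            return UNMATCHED, None
        if self.max_mm == 1 and "N" not in seq:
            idx = self.neighbors.get(seq)
            if idx is None:
                return UNMATCHED, None
            if idx == -1:
                return AMBIGUOUS, None
            return ASSIGNED, self.ids[idx]
        # general path (N-containing reads or max_mm >= 2): scan all entries
        dists = [_hamming(seq, s) for s in self.seqs]
        best = min(dists)
        if best > self.max_mm:
            return UNMATCHED, None
        if dists.count(best) > 1:
            return AMBIGUOUS, None
        return ASSIGNED, self.ids[dists.index(best)]


def match_whitelist(
    barcode_seq: str, whitelist: BarcodeWhitelist, max_mm: int = 1
) -> tuple[str, str | None]:
    """Assign one barcode sequence; returns (status, barcode_id-or-None).

    Status is :data:`ASSIGNED`, :data:`UNMATCHED`, or :data:`AMBIGUOUS`
    (two or more whitelist entries at the minimal distance).
    """
    return _WhitelistMatcher(whitelist, max_mm).match(barcode_seq)


# -- directional UMI collapse ----------------------------------------------

def _hamming1_pairs(codes: np.ndarray, umi_len: int) -> tuple[np.ndarray, np.ndarray]:
    """All ordered index pairs (i, j) with Hamming(codes[i], codes[j]) == 1.

    Codes are base-4 packed integers; only the low ``2*umi_len`` bits vary,
    so higher-order group tags survive intact and pairs never cross groups.
    """
    sorter = np.argsort(codes, kind="stable")
    sorted_codes = codes[sorter]
    srcs, dsts = [], []
    for pos in range(umi_len):
        p = 4**pos
        digit = (codes // p) % 4
        for delta in (1, 2, 3):
            nb = codes + (((digit + delta) % 4) - digit) * p
            idx = np.searchsorted(sorted_codes, nb)
            idx = np.minimum(idx, len(codes) - 1)
            hit = sorted_codes[idx] == nb
            srcs.append(np.nonzero(hit)[0])
            dsts.append(sorter[idx[hit]])
    return np.concatenate(srcs), np.concatenate(dsts)


def _directional_components(
    codes: np.ndarray, counts: np.ndarray, umi_len: int
) -> np.ndarray:
    """Component label per node under the directional scheme.

    Nodes are processed by decreasing count (ties broken by ascending code);
    each unvisited node seeds a component and absorbs everything reachable
    along edges u->v with count(u) >= 2*count(v) - 1 and Hamming(u, v) == 1.
    """
    n = len(codes)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    src, dst = _hamming1_pairs(codes, umi_len)
    keep = counts[src] >= 2 * counts[dst] - 1
    src, dst = src[keep], dst[keep]
    order_e = np.argsort(src, kind="stable")
    src, dst = src[order_e], dst[order_e]
    starts = np.searchsorted(src, np.arange(n))
    ends = np.searchsorted(src, np.arange(n) + 1)

    order = np.lexsort((codes, -counts))
    n_comp = 0
    for root in order:
        if labels[root] != -1:
            continue
        labels[root] = n_comp
        stack = [root]
        while stack:
            u = stack.pop()
            for v in dst[starts[u] : ends[u]]:
                if labels[v] == -1:
                    labels[v] = n_comp
                    stack.append(v)
        n_comp += 1
    return labels


def collapse_umis(umi_counts: Mapping[str, int], method: str = "directional") -> int:
    """Molecule count from a UMI -> read-count mapping.

    ``method="directional"`` merges single-base neighbors per the
    ``count(u) >= 2*count(v) - 1`` rule; ``method="unique"`` counts distinct
    UMIs.  Empty input yields 0.
    """
    if method not in ("directional", "unique"):
        raise ValueError(f"method must be 'directional' or 'unique', got {method!r}")
    if not umi_counts:
        return 0
    lengths = {len(u) for u in umi_counts}
    if len(lengths) != 1:
        raise ValueError("UMIs must have equal length")
    if method == "unique":
        return len(umi_counts)
    umi_len = lengths.pop()
    powers = 4 ** np.arange(umi_len - 1, -1, -1, dtype=np.int64)
    packed = []
    for u in umi_counts:
        codes4 = _BASE_TO_CODE[np.frombuffer(u.encode(), dtype=np.uint8)].astype(np.int64)
        if (codes4 > 3).any():
            raise ValueError(f"non-ACGT UMI {u!r}; drop N-containing UMIs before collapse")
        packed.append(int(codes4 @ powers))
    codes = np.array(packed, dtype=np.int64)
    counts = np.array(list(umi_counts.values()), dtype=np.int64)
    labels = _directional_components(codes, counts, umi_len)
    return int(labels.max()) + 1


@dataclass
class CountTable:
    """Deduplicated molecule counts (barcode x sample) with metadata and QC.

    ``qc`` has one row per sample: reads_in, assigned, unmatched_barcode,
    ambiguous_barcode, anchor_fail, umi_n_dropped, dedup_molecules.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    qc: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns must match sample sheet order")

    @property
    def barcode_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, counts_path, qc_path=None) -> None:
        self.counts.rename_axis("barcode_id").to_csv(counts_path, sep="\t")
        if qc_path is not None:
            self.qc.to_csv(qc_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, sample_sheet: pd.DataFrame, qc_path=None) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col="barcode_id")
        counts = counts[list(sample_sheet["sample_id"])]
        qc = (
            pd.read_csv(qc_path, sep="\t", comment="#")
            if qc_path is not None
            else pd.DataFrame({"sample_id": sample_sheet["sample_id"]})
        )
        return cls(counts=counts, samples=sample_sheet.reset_index(drop=True), qc=qc)


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_batches(path, batch_size: int = _BATCH_READS) -> Iterable[list[str]]:
    batch: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for _name, seq, _qual in FastqGeneralIterator(fh):
            batch.append(seq)
            if len(batch) >= batch_size:
                yield batch
                batch = []
    if batch:
        yield batch


def _encode_barcode_lookup(whitelist: BarcodeWhitelist, max_mm: int):
    """Sorted packed-code arrays for exact and 1-mismatch-neighbor lookup."""
    bc_len = whitelist.barcode_len
    powers = 4 ** np.arange(bc_len - 1, -1, -1, dtype=np.int64)

    def pack(seq: str) -> int:
        return int(_BASE_TO_CODE[np.frombuffer(seq.encode(), np.uint8)].astype(np.int64) @ powers)

    exact_codes = np.array([pack(s) for s in whitelist.sequences], dtype=np.int64)
    exact_order = np.argsort(exact_codes)
    exact_sorted = exact_codes[exact_order]

    nb_sorted = np.empty(0, dtype=np.int64)
    nb_targets = np.empty(0, dtype=np.int64)
    if max_mm >= 1:
        matcher = _WhitelistMatcher(whitelist, max_mm=1)
        items = sorted(matcher.neighbors.items())
        nb_sorted = np.array([pack(s) for s, _ in items], dtype=np.int64)
        nb_targets = np.array([t for _, t in items], dtype=np.int64)
        order = np.argsort(nb_sorted)
        nb_sorted, nb_targets = nb_sorted[order], nb_targets[order]
    return powers, exact_sorted, exact_order, nb_sorted, nb_targets


def _lookup_sorted(sorted_codes: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Index into sorted_codes per query, or -1 when absent."""
    if len(sorted_codes) == 0:
        return np.full(len(queries), -1, dtype=np.int64)
    idx = np.searchsorted(sorted_codes, queries)
    idx = np.minimum(idx, len(sorted_codes) - 1)
    out = np.where(sorted_codes[idx] == queries, idx, -1)
    return out


def _quantify_sample(
    fastq_path,
    whitelist: BarcodeWhitelist,
    layout: ReadLayout,
    anchor_max_mm: int,
    max_mm: int,
    method: str,
) -> tuple[np.ndarray, dict]:
    """One sample: stream reads, assign barcodes, collapse UMIs per barcode."""
    n_bc = len(whitelist.barcode_ids)
    L = layout.total_len
    prefix_bytes = np.frombuffer(layout.prefix_seq.encode(), dtype=np.uint8)
    powers, exact_sorted, exact_order, nb_sorted, nb_targets = _encode_barcode_lookup(
        whitelist, max_mm
    )
    umi_powers = 4 ** np.arange(layout.umi_len - 1, -1, -1, dtype=np.int64)
    umi_space = 4**layout.umi_len
    fallback_matcher = _WhitelistMatcher(whitelist, max_mm) if max_mm >= 1 else None

    qc = {k: 0 for k in ("reads_in", ASSIGNED, UNMATCHED, AMBIGUOUS, ANCHOR_FAIL, "umi_n_dropped")}
    pair_keys: list[np.ndarray] = []

    for batch in _iter_batches(fastq_path):
        qc["reads_in"] += len(batch)
        ok = [s[:L] for s in batch if len(s) >= L]
        qc[ANCHOR_FAIL] += len(batch) - len(ok)
        if not ok:
            continue
        mat = np.frombuffer("".join(ok).encode(), dtype=np.uint8).reshape(len(ok), L)

        prefix_mm = (mat[:, : layout.prefix_len] != prefix_bytes).sum(axis=1)
        anchored = prefix_mm <= anchor_max_mm
        qc[ANCHOR_FAIL] += int((~anchored).sum())
        mat = mat[anchored]
        if not len(mat):
            continue

        bc_codes4 = _BASE_TO_CODE[mat[:, layout.barcode_slice]].astype(np.int64)
        bc_valid = (bc_codes4 <= 3).all(axis=1)
        bc_packed = np.where(bc_valid, bc_codes4.clip(max=3) @ powers, -1)

        # exact, then unique-1-mismatch-neighbor correction
        hit = _lookup_sorted(exact_sorted, bc_packed)
        bc_idx = np.where(hit >= 0, exact_order[hit.clip(min=0)], -1)
        bc_idx[~bc_valid] = -1
        status = np.where(bc_idx >= 0, 0, 1)  # 0 assigned, 1 unmatched, 2 ambiguous
        if max_mm >= 1:
            miss = (bc_idx < 0) & bc_valid
            if miss.any():
                nb_hit = _lookup_sorted(nb_sorted, bc_packed[miss])
                tgt = np.where(nb_hit >= 0, nb_targets[nb_hit.clip(min=0)], -2)
                midx = np.nonzero(miss)[0]
                bc_idx[midx] = np.where(tgt >= 0, tgt, -1)
                status[midx] = np.where(tgt >= 0, 0, np.where(tgt == -1, 2, 1))
        if fallback_matcher is not None and (max_mm >= 2 or (~bc_valid).any()):
            # rare general path: N-containing barcodes or max_mm >= 2
            bc_slice = layout.barcode_slice
            targets = np.nonzero(status != 0)[0] if max_mm >= 2 else np.nonzero(~bc_valid)[0]
            id_index = {bid: i for i, bid in enumerate(whitelist.barcode_ids)}
            for i in targets:
                seq = mat[i, bc_slice].tobytes().decode()
                st, bid = fallback_matcher.match(seq)
                if st == ASSIGNED:
                    status[i] = 0
                    bc_idx[i] = id_index[bid]
                else:
                    status[i] = 1 if st == UNMATCHED else 2

        qc[UNMATCHED] += int((status == 1).sum())
        qc[AMBIGUOUS] += int((status == 2).sum())
        assigned = status == 0
        qc[ASSIGNED] += int(assigned.sum())

        umi_codes4 = _BASE_TO_CODE[mat[assigned][:, layout.umi_slice]].astype(np.int64)
        umi_valid = (umi_codes4 <= 3).all(axis=1)
        qc["umi_n_dropped"] += int((~umi_valid).sum())
        umi_packed = umi_codes4[umi_valid].clip(max=3) @ umi_powers
        pair_keys.append(bc_idx[assigned][umi_valid] * umi_space + umi_packed)

    counts = np.zeros(n_bc, dtype=np.int64)
    if pair_keys:
        keys, reads_per_pair = np.unique(np.concatenate(pair_keys), return_counts=True)
        groups = keys // umi_space
        if method == "unique":
            np.add.at(counts, groups, 1)
        else:
            labels = _directional_components(keys, reads_per_pair, layout.umi_len)
            # one molecule per component; component root group = group of any member
            _, first = np.unique(labels, return_index=True)
            np.add.at(counts, groups[first], 1)
    qc["dedup_molecules"] = int(counts.sum())
    return counts, qc


def build_count_table(
    fastq: Mapping[str, str] | str,
    sample_sheet: pd.DataFrame,
    whitelist: BarcodeWhitelist,
    layout: ReadLayout,
    anchor_max_mm: int = 2,
    max_mm: int = 1,
    method: str = "directional",
    log=None,
) -> CountTable:
    """Quantify every sample in the sheet into a deduplicated CountTable.

    ``fastq`` is either a directory containing ``<sample_id>.fastq[.gz]``
    files or an explicit sample_id -> path mapping.  A sample in the sheet
    with no FASTQ raises an error naming the sample.
    """
    if method not in ("directional", "unique"):
        raise ValueError(f"unknown collapse method {method!r}")
    sample_ids = list(sample_sheet["sample_id"])
    if isinstance(fastq, (str, os.PathLike)):
        paths = {}
        for sid in sample_ids:
            for ext in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
                p = os.path.join(fastq, f"{sid}{ext}")
                if os.path.exists(p):
                    paths[sid] = p
                    break
    else:
        paths = dict(fastq)
    missing = [sid for sid in sample_ids if sid not in paths]
    if missing:
        raise FileNotFoundError(f"no FASTQ for samples: {missing}")

    cols = {}
    qc_rows = []
    for sid in sample_ids:
        counts, qc = _quantify_sample(
            paths[sid], whitelist, layout, anchor_max_mm, max_mm, method
        )
        cols[sid] = counts
        qc_rows.append({"sample_id": sid, **qc})
        if log is not None:
            log(
                f"quantify sample={sid} reads_in={qc['reads_in']} "
                f"assigned={qc[ASSIGNED]} dedup={qc['dedup_molecules']}"
            )
    counts_df = pd.DataFrame(cols, index=pd.Index(whitelist.barcode_ids, name="barcode_id"))
    return CountTable(
        counts=counts_df,
        samples=sample_sheet.reset_index(drop=True),
        qc=pd.DataFrame(qc_rows),
    )
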