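"""Ground-truthed synthetic barcoded-LNP screens.

Generates everything the downstream quantification/enrichment stages need,
with known truth: a barcode whitelist with a minimum pairwise Hamming
distance, a pooled biodistribution with planted organ tropism, and
per-sample FASTQ files with UMIs attached pre-PCR, Bernoulli-doubling PCR
duplication, and i.i.d. per-base substitution errors.

Seeding: one root seed; the random stream for sample *i* is
``default_rng(SeedSequence((root_seed, STREAM_READS, i)))`` and analogous
fixed stream tags for whitelist design and biodistribution draws, so every
artifact is reproducible independently of generation order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORGANS",
    "ReadLayout",
    "BarcodeWhitelist",
    "BiodistributionModel",
    "TruthTable",
    "CapacityError",
    "design_whitelist",
    "simulate_biodistribution",
    "simulate_reads",
    "simulate_screen",
    "per_formulation_dose",
    "encode_seq",
    "decode_seq",
]

#: Fixed organ order used everywhere downstream.
ORGANS = ("heart", "liver", "spleen", "lung", "kidney")

NAKED_ID = "naked"
NAKED_LNP = "naked_control"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i

# stream tags for per-purpose child seeds
_STREAM_WHITELIST = 0
_STREAM_BIODIST = 1
_STREAM_READS = 2


def _rng(root_seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(root_seed), stream, int(index))))


def encode_seq(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3 (raises on other characters)."""
    codes = _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError(f"non-ACGT character in sequence {seq!r}")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


class CapacityError(RuntimeError):
    """Whitelist design could not place the requested number of barcodes."""


@dataclass(frozen=True)
class ReadLayout:
    """Positional read layout: prefix | barcode | UMI | suffix (0-based, half-open)."""

    prefix_seq: str = "ACGCTCTTCCGATCTAGCAT"  # 20 nt
    barcode_len: int = 8
    umi_len: int = 8
    suffix_seq: str = "AGATCGGAAGAGCACACGTC"  # 20 nt

    @property
    def prefix_len(self) -> int:
        return len(self.prefix_seq)

    @property
    def suffix_len(self) -> int:
        return len(self.suffix_seq)

    @property
    def total_len(self) -> int:
        return self.prefix_len + self.barcode_len + self.umi_len + self.suffix_len

    @property
    def barcode_slice(self) -> slice:
        return slice(self.prefix_len, self.prefix_len + self.barcode_len)

    @property
    def umi_slice(self) -> slice:
        start = self.prefix_len + self.barcode_len
        return slice(start, start + self.umi_len)

    def to_dict(self) -> dict:
        return {
            "prefix_seq": self.prefix_seq,
            "barcode_len": self.barcode_len,
            "umi_len": self.umi_len,
            "suffix_seq": self.suffix_seq,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReadLayout":
        return cls(
            prefix_seq=str(d.get("prefix_seq", cls.prefix_seq)),
            barcode_len=int(d.get("barcode_len", cls.barcode_len)),
            umi_len=int(d.get("umi_len", cls.umi_len)),
            suffix_seq=str(d.get("suffix_seq", cls.suffix_seq)),
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best


@dataclass
class BarcodeWhitelist:
    """Barcode id <-> sequence <-> LNP formulation mapping with distance guarantees."""

    entries: pd.DataFrame  # columns: barcode_id, sequence, lnp_name
    min_pairwise_hamming: int

    def __post_init__(self) -> None:
        required = {"barcode_id", "sequence", "lnp_name"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"whitelist needs columns {sorted(required)}")
        seqs = list(self.entries["sequence"])
        if len(set(seqs)) != len(seqs):
            raise ValueError("whitelist sequences are not unique")
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("whitelist sequences have mixed lengths")
        naked = self.entries["lnp_name"] == NAKED_LNP
        if naked.sum() > 1:
            raise ValueError("at most one naked-control entry allowed")

    @property
    def barcode_len(self) -> int:
        return len(self.entries["sequence"].iloc[0])

    @property
    def barcode_ids(self) -> list[str]:
        return list(self.entries["barcode_id"])

    @property
    def sequences(self) -> list[str]:
        return list(self.entries["sequence"])

    def sequence_of(self, barcode_id: str) -> str:
        row = self.entries.loc[self.entries["barcode_id"] == barcode_id, "sequence"]
        if row.empty:
            raise KeyError(barcode_id)
        return row.iloc[0]

    def verify_min_distance(self) -> int:
        """Brute-force minimum pairwise Hamming distance over all entries."""
        seqs = self.sequences
        if len(seqs) < 2:
            return self.barcode_len
        return min(
            _hamming(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        )

    def with_lnp_names(self, names: Sequence[str]) -> "BarcodeWhitelist":
        """Attach formulation names to non-naked entries, in whitelist order."""
        entries = self.entries.copy()
        mask = entries["lnp_name"] != NAKED_LNP
        if mask.sum() != len(names):
            raise ValueError(f"need {mask.sum()} names, got {len(names)}")
        entries.loc[mask, "lnp_name"] = list(names)
        return BarcodeWhitelist(entries=entries, min_pairwise_hamming=self.min_pairwise_hamming)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, min_pairwise_hamming: int | None = None) -> "BarcodeWhitelist":
        entries = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        wl = cls(entries=entries, min_pairwise_hamming=0)
        d = wl.verify_min_distance() if min_pairwise_hamming is None else min_pairwise_hamming
        wl.min_pairwise_hamming = d
        return wl


def design_whitelist(
    n: int,
    barcode_len: int = 8,
    min_dist: int = 3,
    seed: int = 0,
    include_naked_control: bool = False,
    max_attempts_per_code: int = 20_000,
) -> BarcodeWhitelist:
    """Rejection-sample ``n`` barcodes at pairwise Hamming distance >= ``min_dist``.

    Candidates with a homopolymer run longer than 3 are rejected.  When
    ``include_naked_control`` is set, one extra barcode is drawn and labelled
    as the naked (unencapsulated) control.  Deterministic given ``seed``.
    """
    n_total = n + int(include_naked_control)
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_dist < 1:
        raise ValueError("min_dist must be >= 1")
    if n_total > 1 and min_dist > barcode_len:
        raise CapacityError(
            f"min_dist {min_dist} exceeds barcode length {barcode_len}; "
            f"cannot place {n_total} codes"
        )
    rng = _rng(seed, _STREAM_WHITELIST)
    accepted: list[str] = []
    budget = max_attempts_per_code * n_total
    attempts = 0
    while len(accepted) < n_total:
        if attempts >= budget:
            raise CapacityError(
                f"placed only {len(accepted)}/{n_total} barcodes of length "
                f"{barcode_len} at min distance {min_dist} within {budget} attempts"
            )
        attempts += 1
        candidate = decode_seq(rng.integers(0, 4, size=barcode_len).astype(np.uint8))
        if _max_homopolymer_run(candidate) > 3:
            continue
        if all(_hamming(candidate, s) >= min_dist for s in accepted):
            accepted.append(candidate)

    ids = [f"bc{i + 1:03d}" for i in range(n)]
    lnps = [f"LNP{i + 1}" for i in range(n)]
    if include_naked_control:
        ids.append(NAKED_ID)
        lnps.append(NAKED_LNP)
    entries = pd.DataFrame({"barcode_id": ids, "sequence": accepted, "lnp_name": lnps})
    return BarcodeWhitelist(entries=entries, min_pairwise_hamming=min_dist)


@dataclass
class BiodistributionModel:
    """Generative model for the pooled screen.

    ``organ_affinity`` rows are barcodes, columns organs; 1 is neutral,
    >1 planted enrichment, <1 depletion.  Expected count for
    (mouse, organ, barcode) is ``molecules_per_organ`` times the
    affinity-reweighted pool fraction, jittered by log-normal per-(mouse,
    barcode, organ) noise, realized as a Poisson draw.
    """

    pool_fractions: pd.Series
    organ_affinity: pd.DataFrame
    mouse_sd: float = 0.3
    molecules_per_organ: int = 20_000
    pcr_cycles: int = 2
    pcr_efficiency: float = 0.5
    seq_error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(self.pool_fractions.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool_fractions must sum to 1 (got {total!r})")
        if (self.pool_fractions < 0).any():
            raise ValueError("pool_fractions must be non-negative")
        if (self.organ_affinity <= 0).to_numpy().any():
            raise ValueError("all organ affinities must be > 0")
        if not 0 <= self.pcr_efficiency <= 1:
            raise ValueError("pcr_efficiency must be in [0, 1]")
        if not 0 <= self.seq_error_rate <= 1:
            raise ValueError("seq_error_rate must be in [0, 1]")
        if self.mouse_sd < 0:
            raise ValueError("mouse_sd must be >= 0")

    @classmethod
    def neutral(
        cls,
        whitelist: BarcodeWhitelist,
        organs: Sequence[str] = ORGANS,
        **kwargs,
    ) -> "BiodistributionModel":
        """Uniform pool, affinity 1 everywhere (the null model)."""
        ids = whitelist.barcode_ids
        frac = pd.Series(1.0 / len(ids), index=ids)
        aff = pd.DataFrame(1.0, index=ids, columns=list(organs))
        return cls(pool_fractions=frac, organ_affinity=aff, **kwargs)

    def with_planted_tropism(
        self,
        barcode_ids: Sequence[str],
        organ: str,
        fold: float,
    ) -> "BiodistributionModel":
        aff = self.organ_affinity.copy()
        aff.loc[list(barcode_ids), organ] = fold
        return replace(self, organ_affinity=aff)

    def tropism_labels(self) -> pd.Series:
        """Per-barcode planted label: '<organ>_enriched'/'<organ>_depleted' or 'neutral'."""
        labels = {}
        for bc in self.organ_affinity.index:
            row = self.organ_affinity.loc[bc]
            if (row > 1).any():
                labels[bc] = f"{row.idxmax()}_enriched"
            elif (row < 1).any():
                labels[bc] = f"{row.idxmin()}_depleted"
            else:
                labels[bc] = "neutral"
        return pd.Series(labels, name="tropism")


@dataclass
class TruthTable:
    """True pre-PCR molecule counts per sample, plus planted tropism labels.

    ``counts``: barcode x sample matrix of non-negative integers.
    ``samples``: sample metadata (sample_id, mouse, organ, role).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    tropism: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("truth counts must be non-negative")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("truth columns must match sample sheet order")

    def to_tsv(self, counts_path, samples_path) -> None:
        self.counts.rename_axis("barcode_id").to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)


def simulate_biodistribution(
    model: BiodistributionModel,
    whitelist: BarcodeWhitelist,
    n_mice: int = 5,
    organs: Sequence[str] = ORGANS,
) -> TruthTable:
    """Draw true molecule counts for every (mouse, organ) tissue sample."""
    if not organs:
        raise ValueError("organ list must be non-empty")
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    ids = whitelist.barcode_ids
    frac = model.pool_fractions.reindex(ids)
    if frac.isna().any():
        raise ValueError("pool_fractions missing whitelist barcodes")
    aff = model.organ_affinity.reindex(index=ids, columns=list(organs))
    if aff.isna().to_numpy().any():
        raise ValueError("organ_affinity missing whitelist barcodes or organs")

    rng = _rng(model.seed, _STREAM_BIODIST)
    cols: dict[str, np.ndarray] = {}
    meta = []
    for mouse in range(1, n_mice + 1):
        for organ in organs:
            w = frac.to_numpy() * aff[organ].to_numpy()
            expected = model.molecules_per_organ * w / w.sum()
            noise = np.exp(rng.normal(0.0, model.mouse_sd, size=len(ids)))
            counts = rng.poisson(expected * noise)
            sample_id = f"m{mouse}_{organ}"
            cols[sample_id] = counts
            meta.append({"sample_id": sample_id, "mouse": mouse, "organ": organ, "role": "tissue"})
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="barcode_id"))
    samples = pd.DataFrame(meta)
    return TruthTable(counts=counts, samples=samples, tropism=model.tropism_labels())


def _extend_with_references(
    truth: TruthTable,
    model: BiodistributionModel,
    whitelist: BarcodeWhitelist,
    pool_replicates: int,
    naked_reference: bool,
) -> TruthTable:
    """Append uninjected-pool replicate(s) and an optional naked-only reference sample."""
    rng = _rng(model.seed, _STREAM_BIODIST, index=1)
    ids = whitelist.barcode_ids
    frac = model.pool_fractions.reindex(ids).to_numpy()
    counts = truth.counts.copy()
    meta = [dict(r) for r in truth.samples.to_dict("records")]
    for rep in range(1, pool_replicates + 1):
        sid = "pool" if pool_replicates == 1 else f"pool{rep}"
        counts[sid] = rng.poisson(model.molecules_per_organ * frac)
        meta.append({"sample_id": sid, "mouse": 0, "organ": "none", "role": "pool"})
    if naked_reference:
        naked_ids = set(
            whitelist.entries.loc[whitelist.entries["lnp_name"] == NAKED_LNP, "barcode_id"]
        )
        mask = truth.counts.index.isin(naked_ids)
        vec = np.zeros(len(ids), dtype=np.int64)
        vec[mask] = rng.poisson(model.molecules_per_organ)
        counts["naked_ref"] = vec
        meta.append({"sample_id": "naked_ref", "mouse": 0, "organ": "none", "role": "naked"})
    return TruthTable(counts=counts, samples=pd.DataFrame(meta), tropism=truth.tropism)


def simulate_screen(
    model: BiodistributionModel,
    whitelist: BarcodeWhitelist,
    n_mice: int = 5,
    organs: Sequence[str] = ORGANS,
    pool_replicates: int = 1,
    naked_reference: bool = True,
) -> TruthTable:
    """Tissue truth plus uninjected-pool and naked-control reference samples."""
    if pool_replicates < 1:
        raise ValueError("pool_replicates must be >= 1")
    truth = simulate_biodistribution(model, whitelist, n_mice=n_mice, organs=organs)
    return _extend_with_references(truth, model, whitelist, pool_replicates, naked_reference)


def _serial_digit_matrix(n: int, width: int) -> np.ndarray:
    """uint8 ASCII digits of 0..n-1, zero-padded to ``width`` columns."""
    serial = np.arange(n, dtype=np.int64)
    out = np.empty((n, width), dtype=np.uint8)
    for col in range(width - 1, -1, -1):
        out[:, col] = ord("0") + serial % 10
        serial //= 10
    return out


def _pcr_copies(n_molecules: int, cycles: int, efficiency: float, rng) -> np.ndarray:
    copies = np.ones(n_molecules, dtype=np.int64)
    for _ in range(cycles):
        copies += rng.binomial(copies, efficiency)
    return copies


def simulate_reads(
    truth: TruthTable,
    layout: ReadLayout,
    whitelist: BarcodeWhitelist,
    model: BiodistributionModel,
    out_dir,
    emit_read_truth: bool = False,
) -> pd.DataFrame:
    """Write one FASTQ per sample; return a manifest DataFrame.

    Each true molecule receives one UMI drawn uniformly over ``4**umi_len``,
    is duplicated through ``pcr_cycles`` Bernoulli(``pcr_efficiency``)
    doubling rounds, and every output read suffers i.i.d. per-base
    substitutions at ``seq_error_rate``.  Quality is the constant 'I'.
    Deterministic given the model seed.
    """
    if layout.barcode_len != whitelist.barcode_len:
        raise ValueError(
            f"layout barcode_len {layout.barcode_len} != whitelist "
            f"barcode length {whitelist.barcode_len}"
        )
    os.makedirs(out_dir, exist_ok=True)
    L = layout.total_len
    umi_space = 4 ** layout.umi_len
    prefix = encode_seq(layout.prefix_seq)
    suffix = encode_seq(layout.suffix_seq)
    bc_codes = np.stack([encode_seq(s) for s in whitelist.sequences])  # (n_bc, bc_len)
    ids = whitelist.barcode_ids

    manifest = []
    truth_rows = []
    for sample_pos, sample_id in enumerate(truth.counts.columns):
        rng = _rng(model.seed, _STREAM_READS, index=sample_pos)
        counts = truth.counts[sample_id].reindex(ids).fillna(0).astype(np.int64).to_numpy()
        n_mol = int(counts.sum())
        mol_barcode = np.repeat(np.arange(len(ids)), counts)
        mol_umi = rng.integers(0, umi_space, size=n_mol, dtype=np.int64)
        copies = _pcr_copies(n_mol, model.pcr_cycles, model.pcr_efficiency, rng)
        read_barcode = np.repeat(mol_barcode, copies)
        read_umi = np.repeat(mol_umi, copies)
        read_mol = np.repeat(np.arange(n_mol), copies)
        n_reads = int(copies.sum())

        # assemble encoded base matrix
        seq = np.empty((n_reads, L), dtype=np.uint8)
        seq[:, : layout.prefix_len] = prefix
        seq[:, layout.barcode_slice] = bc_codes[read_barcode]
        umi_block = np.empty((n_reads, layout.umi_len), dtype=np.uint8)
        u = read_umi.copy()
        for col in range(layout.umi_len - 1, -1, -1):
            umi_block[:, col] = u % 4
            u //= 4
        seq[:, layout.umi_slice] = umi_block
        seq[:, layout.prefix_len + layout.barcode_len + layout.umi_len :] = suffix

        # substitution errors at random flat positions (with-replacement draw;
        # duplicate positions are vanishingly rare at realistic error rates)
        n_err = rng.binomial(n_reads * L, model.seq_error_rate) if n_reads else 0
        if n_err:
            flat = rng.integers(0, n_reads * L, size=n_err)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            flat_seq = seq.reshape(-1)
            flat_seq[flat] = (flat_seq[flat] + shift) % 4

        # fixed-width FASTQ records: @r<9 digits>\n seq\n +\n qual\n
        name_w = 9
        rec_len = (2 + name_w + 1) + (L + 1) + 2 + (L + 1)
        rec = np.empty((n_reads, rec_len), dtype=np.uint8)
        rec[:, 0] = ord("@")
        rec[:, 1] = ord("r")
        rec[:, 2 : 2 + name_w] = _serial_digit_matrix(n_reads, name_w)
        rec[:, 2 + name_w] = ord("\n")
        s0 = 2 + name_w + 1
        rec[:, s0 : s0 + L] = _BASES[seq]
        rec[:, s0 + L] = ord("\n")
        rec[:, s0 + L + 1] = ord("+")
        rec[:, s0 + L + 2] = ord("\n")
        q0 = s0 + L + 3
        rec[:, q0 : q0 + L] = ord("I")
        rec[:, q0 + L] = ord("\n")

        fastq_path = os.path.join(out_dir, f"{sample_id}.fastq")
        with open(fastq_path, "wb") as fh:
            fh.write(rec.tobytes())
        manifest.append(
            {
                "sample_id": sample_id,
                "fastq": fastq_path,
                "n_molecules": n_mol,
                "n_reads": n_reads,
            }
        )
        if emit_read_truth:
            truth_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "read_id": [f"r{i:09d}" for i in range(n_reads)],
                        "true_barcode_id": [ids[b] for b in read_barcode],
                        "true_umi": read_umi,
                        "molecule_index": read_mol,
                    }
                )
            )

    manifest_df = pd.DataFrame(manifest)
    if emit_read_truth:
        pd.concat(truth_rows, ignore_index=True).to_csv(
            os.path.join(out_dir, "read_truth.tsv"), sep="\t", index=False
        )
    return manifest_df


def per_formulation_dose(total_dose_mg_per_kg: float, n_formulations: int) -> float:
    """Average per-formulation dose when a total dose is split evenly over a pool."""
    if n_formulations < 1:
        raise ValueError("n_formulations must be >= 1")
    if total_dose_mg_per_kg < 0:
        raise ValueError("dose must be >= 0")
    return total_dose_mg_per_kg / n_formulations
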