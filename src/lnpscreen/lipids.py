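"""Combinatorial CAD lipid library and in vitro hit-rate (SAR) analysis.

The library is the cross product of an amine-core registry and an
aldehyde-tail registry.  Each member is named ``<core_id>-<tail_code>``
where the tail code follows the grammar ``A<y>-<Z>[b|b2]``: ``y`` is the
number of tails, ``Z`` the carbon count per tail, and an optional suffix
marks the branching class.

Hit calling operates on a replicate-level RLU table (relative luminescence
units, PBS-normalized): a lipid is a hit when its aggregated RLU strictly
exceeds a threshold (default 100).  Hit rates are tabulated against
structural features using either a whole-library or a within-group
denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AmineCore",
    "AldehydeTail",
    "LipidDescriptor",
    "RegistryError",
    "LipidNameError",
    "default_core_registry",
    "default_tail_registry",
    "enumerate_library",
    "parse_lipid_name",
    "parse_tail_code",
    "classify_hits",
    "hit_rate_by_feature",
    "load_core_registry",
    "load_tail_registry",
    "load_rlu_table",
    "FEATURES",
]

BRANCH_LINEAR = "linear"
BRANCH_B = "branched_b"
BRANCH_B2 = "branched_b2"

FEATURES = ("secondary_amine_count", "branch_class", "tail_number", "tail_length")


class RegistryError(ValueError):
    """Duplicate or invalid registry entries."""


class LipidNameError(ValueError):
    """A lipid or tail name does not follow the naming grammar."""


@dataclass(frozen=True)
class AmineCore:
    """One amine head of the combinatorial library.

    ``secondary_amine_count`` is registry-supplied annotation (number of
    secondary amines in the final lipid), not computed from chemistry.
    """

    core_id: int
    name: str
    secondary_amine_count: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.secondary_amine_count < 1:
            raise RegistryError(
                f"core {self.core_id}: secondary_amine_count must be >= 1, "
                f"got {self.secondary_amine_count}"
            )


@dataclass(frozen=True)
class AldehydeTail:
    """One aldehyde degradable tail, identified by its code (e.g. ``A2-7b2``)."""

    tail_code: str
    tail_number: int
    tail_length: int
    branch_class: str

    @classmethod
    def from_code(cls, code: str) -> "AldehydeTail":
        number, length, branch = parse_tail_code(code)
        return cls(tail_code=code, tail_number=number, tail_length=length, branch_class=branch)

    def __post_init__(self) -> None:
        parsed = parse_tail_code(self.tail_code)
        if parsed != (self.tail_number, self.tail_length, self.branch_class):
            raise RegistryError(
                f"tail {self.tail_code!r}: fields {parsed} inconsistent with code"
            )


@dataclass(frozen=True)
class LipidDescriptor:
    """One library member: a (core, tail) pair named ``<core_id>-<tail_code>``."""

    name: str
    core: AmineCore
    tail: AldehydeTail

    def feature(self, feature: str):
        if feature == "secondary_amine_count":
            return self.core.secondary_amine_count
        if feature == "branch_class":
            return self.tail.branch_class
        if feature == "tail_number":
            return self.tail.tail_number
        if feature == "tail_length":
            return self.tail.tail_length
        raise KeyError(f"unknown feature {feature!r}; expected one of {FEATURES}")


_TAIL_RE = re.compile(r"^A([23])-(\d+)(b2|b)?$")
_LIPID_RE = re.compile(r"^(\d+)-(A[23]-\d+(?:b2|b)?)$")

_BRANCH_BY_SUFFIX = {None: BRANCH_LINEAR, "b": BRANCH_B, "b2": BRANCH_B2}


def parse_tail_code(code: str) -> tuple[int, int, str]:
    """Parse a tail code into (tail_number, tail_length, branch_class)."""
    m = _TAIL_RE.match(code)
    if m is None:
        raise LipidNameError(f"malformed tail code {code!r}: expected A<2|3>-<int>[b|b2]")
    return int(m.group(1)), int(m.group(2)), _BRANCH_BY_SUFFIX[m.group(3)]


def parse_lipid_name(name: str) -> tuple[int, str, int, int, str]:
    """Parse ``X-Ay-Z`` into (core_id, tail_code, tail_number, tail_length, branch_class).

    >>> parse_lipid_name("5-A2-7b2")
    (5, 'A2-7b2', 2, 7, 'branched_b2')
    """
    m = _LIPID_RE.match(name)
    if m is None:
        raise LipidNameError(
            f"malformed lipid name {name!r}: expected <core_id>-A<2|3>-<int>[b|b2]"
        )
    core_id = int(m.group(1))
    tail_code = m.group(2)
    tail_number, tail_length, branch_class = parse_tail_code(tail_code)
    return core_id, tail_code, tail_number, tail_length, branch_class


# Default registries. Core names follow the materials list; the
# secondary-amine annotation counts secondary amines in the final lipid
# (primary amines become secondary upon reductive amination) and is
# editable registry data, not derived chemistry.
_DEFAULT_CORES: tuple[tuple[int, str, int], ...] = (
    (1, "2,2'-diamino-N-methyldiethylamine", 2),
    (2, "3,3'-diamino-N-methyldipropylamine", 2),
    (3, "2,2'-(piperazine-1,4-diyl)diethanamine", 2),
    (4, "1,4-bis(3-aminopropyl)piperazine", 2),
    (5, "N,N-dimethylethylenediamine", 1),
    (6, "N,N-dimethyl-1,3-propanediamine", 1),
    (7, "N,N-diethylethylenediamine", 1),
    (8, "N,N-diethyl-1,3-diaminopropane", 1),
    (9, "1-(2-aminoethyl)-4-methylpiperazine", 1),
    (10, "1-(3-aminopropyl)-4-methylpiperazine", 1),
    (11, "1,3-diaminopropane", 2),
    (12, "tris(2-aminoethyl)amine", 3),
)

# Synthesis order: di-degradable tails first, then tri-degradable.
_DEFAULT_TAIL_CODES: tuple[str, ...] = (
    "A2-6", "A2-6b", "A2-7", "A2-7b", "A2-7b2",
    "A2-8", "A2-8b", "A2-9", "A2-9b", "A2-9b2",
    "A3-6b", "A3-7b", "A3-7b2", "A3-8b", "A3-9b2",
)


def default_core_registry() -> list[AmineCore]:
    """The 12 default amine cores."""
    return [AmineCore(core_id=i, name=n, secondary_amine_count=s) for i, n, s in _DEFAULT_CORES]


def default_tail_registry() -> list[AldehydeTail]:
    """The 15 default aldehyde tails, in synthesis order."""
    return [AldehydeTail.from_code(c) for c in _DEFAULT_TAIL_CODES]


def _check_unique(values: Iterable, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise RegistryError(f"duplicate {what}: {v!r}")
        seen.add(v)


def enumerate_library(
    cores: Sequence[AmineCore] | None = None,
    tails: Sequence[AldehydeTail] | None = None,
) -> list[LipidDescriptor]:
    """Enumerate the full combinatorial library, core-major, tails in registry order.

    Returns ``len(cores) * len(tails)`` descriptors with unique names.
    """
    if cores is None:
        cores = default_core_registry()
    if tails is None:
        tails = default_tail_registry()
    if not cores or not tails:
        raise RegistryError("core and tail registries must be non-empty")
    _check_unique((c.core_id for c in cores), "core_id")
    _check_unique((t.tail_code for t in tails), "tail_code")
    return [
        LipidDescriptor(name=f"{core.core_id}-{tail.tail_code}", core=core, tail=tail)
        for core in cores
        for tail in tails
    ]


def classify_hits(
    rlu: pd.DataFrame,
    threshold: float = 100.0,
    agg: str = "mean",
) -> pd.Series:
    """Flag hits: aggregated replicate RLU strictly greater than ``threshold``.

    Parameters
    ----------
    rlu
        Long-format table with columns ``lipid_name``, ``replicate``, ``rlu``.
    threshold
        Hit threshold on the aggregated RLU (strict inequality).
    agg
        Replicate aggregator, ``"mean"`` (default) or ``"median"``.

    Returns
    -------
    Boolean Series indexed by lipid name.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if agg not in ("mean", "median"):
        raise ValueError(f"agg must be 'mean' or 'median', got {agg!r}")
    required = {"lipid_name", "rlu"}
    if not required.issubset(rlu.columns):
        raise ValueError(f"RLU table must have columns {sorted(required)}")
    if (rlu["rlu"] < 0).any():
        raise ValueError("RLU values must be >= 0")
    if rlu.empty:
        raise ValueError("RLU table has no replicates")
    aggregated = rlu.groupby("lipid_name")["rlu"].agg(agg)
    return aggregated > threshold


def hit_rate_by_feature(
    hits: Mapping[str, bool] | pd.Series,
    library: Sequence[LipidDescriptor],
    feature: str,
    denominator: str = "library",
) -> pd.DataFrame:
    """Tabulate the relative hit rate against one structural feature.

    With ``denominator="library"`` (default) the rate at each feature level
    is ``100 * (#hits at level) / len(library)``, so rates across levels sum
    to the overall hit percentage.  With ``denominator="within"`` the rate is
    ``100 * (#hits at level) / (#library members at level)``.

    Returns a DataFrame with columns ``level``, ``n_lipids``, ``n_hits``,
    ``hit_rate_pct``, sorted by level.
    """
    if feature not in FEATURES:
        raise KeyError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    if denominator not in ("library", "within"):
        raise ValueError(f"denominator must be 'library' or 'within', got {denominator!r}")
    by_name = {d.name: d for d in library}
    hits = pd.Series(hits, dtype=bool)
    unknown = [k for k in hits.index if k not in by_name]
    if unknown:
        raise KeyError(f"hit keys not in library: {unknown[:5]}")

    levels: dict = {}
    for d in library:
        lvl = d.feature(feature)
        levels.setdefault(lvl, [0, 0])
        levels[lvl][0] += 1
    for name, flag in hits.items():
        if flag:
            levels[by_name[name].feature(feature)][1] += 1

    rows = []
    for lvl in sorted(levels):
        n_lipids, n_hits = levels[lvl]
        denom = len(library) if denominator == "library" else n_lipids
        rows.append(
            {
                "level": lvl,
                "n_lipids": n_lipids,
                "n_hits": n_hits,
                "hit_rate_pct": 100.0 * n_hits / denom,
            }
        )
    return pd.DataFrame(rows)


# -- TSV interfaces ---------------------------------------------------------

def load_core_registry(path) -> list[AmineCore]:
    """Read an amine-core registry TSV: core_id, name, secondary_amine_count[, note]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AmineCore(
            core_id=int(r.core_id),
            name=str(r.name),
            secondary_amine_count=int(r.secondary_amine_count),
            note=str(getattr(r, "note", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]


def load_tail_registry(path) -> list[AldehydeTail]:
    """Read a tail registry TSV with a tail_code column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [AldehydeTail.from_code(str(c)) for c in df["tail_code"]]


def load_rlu_table(path) -> pd.DataFrame:
    """Read a replicate-level RLU TSV: lipid_name, replicate, rlu."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"lipid_name", "replicate", "rlu"} - set(df.columns)
    if missing:
        raise ValueError(f"RLU table missing columns: {sorted(missing)}")
    return df
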