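"""Subset models of the 14-assay androgen-receptor (AR) pathway battery.

The AR pathway model combines 14 high-throughput in vitro assays (indexed
A1..A14).  A *subset model* is the AR model rebuilt from a chosen subset of
those assays, written as ``"A"`` followed by 14 binary digits where digit *i*
(left to right) marks the inclusion of assay A*i*.  For example,
``A10000000001111`` contains assays A1, A11, A12, A13 and A14.

Each subset model decomposes into two mode-specific pathways:

* the **agonist** pathway draws on assays A1–A11;
* the **antagonist** pathway draws on assays A1–A6 and A12–A14.

The two pathways share the upstream receptor-binding, coregulator-recruitment
and nuclear-translocation steps (A1–A6); A7–A11 are agonist-only readouts and
A12–A14 antagonist-only readouts.  This module provides the nomenclature
parser/formatter, enumeration of all subset models, pathway decomposition,
and the set algebra (union size, Hamming distance) used by the battery
optimizer.

Bit-order convention: position 1 is the leftmost character after the ``"A"``
prefix, i.e. the name reads A1..A14 left to right.  The integer ``mask`` of a
model reads A1 as the most significant bit, so enumeration "ascending by
integer value" sorts names lexicographically as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

NUM_ASSAYS = 14

#: Assay indices (1-based) feeding the full agonist pathway (R1).
AGONIST_PATHWAY: frozenset[int] = frozenset(range(1, 12))

#: Assay indices (1-based) feeding the full antagonist pathway (R2).
ANTAGONIST_PATHWAY: frozenset[int] = frozenset({1, 2, 3, 4, 5, 6, 12, 13, 14})

MODES = ("agonist", "antagonist")

Mode = Literal["agonist", "antagonist"]


class ModelNameError(ValueError):
    """Raised when a subset-model nomenclature string is malformed."""


@dataclass(frozen=True)
class Assay:
    """One assay endpoint of the 14-assay battery.

    Parameters
    ----------
    index
        1-based position A1..A14.
    endpoint_name
        The assay endpoint identifier (e.g. ``"NVS_NR_hAR"``).
    role
        Biological role of the readout; one of :data:`ASSAY_ROLES`.
    """

    index: int
    endpoint_name: str
    role: str

    @property
    def label(self) -> str:
        return f"A{self.index}"


ASSAY_ROLES = frozenset(
    {
        "receptor-binding",
        "coregulator-recruitment",
        "nuclear-translocation-agonist",
        "nuclear-translocation-antagonist",
        "RNA-reporter",
        "protein-reporter-agonist",
        "protein-reporter-antagonist",
        "proliferation",
    }
)

# Default endpoint names for A1..A14 with their biological roles.
_DEFAULT_ASSAYS = (
    (1, "NVS_NR_hAR", "receptor-binding"),
    (2, "NVS_NR_cAR", "receptor-binding"),
    (3, "NVS_NR_rAR", "receptor-binding"),
    (4, "OT_AR_ARSRC1_0480", "coregulator-recruitment"),
    (5, "OT_AR_ARSRC1_0960", "coregulator-recruitment"),
    (6, "UPITT_HCI_U2OS_AR_TIF2_Nucleoli_Agonist", "nuclear-translocation-agonist"),
    (7, "ATG_AR_TRANS_up", "RNA-reporter"),
    (8, "OT_AR_ARELUC_AG_1440", "protein-reporter-agonist"),
    (9, "TOX21_AR_BLA_Agonist_ratio", "protein-reporter-agonist"),
    (10, "TOX21_AR_LUC_MDAKB2_Agonist", "protein-reporter-agonist"),
    (11, "ACEA_AR_agonist_80h", "proliferation"),
    (12, "UPITT_HCI_U2OS_AR_TIF2_Nucleoli_Antagonist", "nuclear-translocation-antagonist"),
    (13, "TOX21_AR_BLA_Antagonist_ratio", "protein-reporter-antagonist"),
    (14, "TOX21_AR_LUC_MDAKB2_Antagonist_0.5 nM_R1881", "protein-reporter-antagonist"),
)


@dataclass(frozen=True)
class AssayRoster:
    """The ordered 14-assay roster with its two mode pathways.

    Invariants enforced at construction: exactly 14 assays; the agonist and
    antagonist pathways overlap exactly on A1–A6; A7–A11 appear only in the
    agonist pathway and A12–A14 only in the antagonist pathway.
    """

    assays: tuple[Assay, ...]
    agonist_pathway: frozenset[int] = field(default=AGONIST_PATHWAY)
    antagonist_pathway: frozenset[int] = field(default=ANTAGONIST_PATHWAY)

    def __post_init__(self) -> None:
        if len(self.assays) != NUM_ASSAYS:
            raise ValueError(f"roster must contain exactly {NUM_ASSAYS} assays, got {len(self.assays)}")
        indices = tuple(a.index for a in self.assays)
        if indices != tuple(range(1, NUM_ASSAYS + 1)):
            raise ValueError("roster assays must be ordered A1..A14 by index")
        for a in self.assays:
            if a.role not in ASSAY_ROLES:
                raise ValueError(f"unknown role {a.role!r} for assay {a.label}")
        overlap = self.agonist_pathway & self.antagonist_pathway
        if overlap != frozenset(range(1, 7)):
            raise ValueError("agonist and antagonist pathways must overlap exactly on A1..A6")
        if not (self.agonist_pathway - self.antagonist_pathway) <= frozenset(range(7, 12)):
            raise ValueError("agonist-only assays must be A7..A11")
        if not (self.antagonist_pathway - self.agonist_pathway) <= frozenset(range(12, 15)):
            raise ValueError("antagonist-only assays must be A12..A14")

    def pathway(self, mode: Mode) -> frozenset[int]:
        """Assay indices of the full pathway for ``mode``."""
        if mode == "agonist":
            return self.agonist_pathway
        if mode == "antagonist":
            return self.antagonist_pathway
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")

    def endpoint(self, index: int) -> str:
        return self.assays[index - 1].endpoint_name


def default_roster() -> AssayRoster:
    """The default roster with the published A1..A14 endpoint names."""
    return AssayRoster(assays=tuple(Assay(i, n, r) for i, n, r in _DEFAULT_ASSAYS))


@dataclass(frozen=True, order=True)
class SubsetModel:
    """A subset of the 14 assays, identified by a 14-bit membership vector.

    ``membership[i]`` is 1 iff assay A(i+1) is included.  The nomenclature
    string is ``"A"`` + the 14 membership bits, A1 leftmost.
    """

    membership: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.membership) != NUM_ASSAYS:
            raise ValueError(f"membership must have {NUM_ASSAYS} entries, got {len(self.membership)}")
        if any(b not in (0, 1) for b in self.membership):
            raise ValueError("membership entries must be 0 or 1")

    @classmethod
    def from_assays(cls, assays: Iterable[int]) -> "SubsetModel":
        """Build a model from 1-based assay indices."""
        idx = set(assays)
        bad = idx - set(range(1, NUM_ASSAYS + 1))
        if bad:
            raise ValueError(f"assay indices out of range 1..{NUM_ASSAYS}: {sorted(bad)}")
        return cls(tuple(1 if i in idx else 0 for i in range(1, NUM_ASSAYS + 1)))

    @classmethod
    def from_mask(cls, mask: int) -> "SubsetModel":
        """Build a model from its integer mask (A1 = most significant bit)."""
        if not 0 <= mask < (1 << NUM_ASSAYS):
            raise ValueError(f"mask out of range: {mask}")
        return cls(tuple((mask >> (NUM_ASSAYS - 1 - i)) & 1 for i in range(NUM_ASSAYS)))

    @property
    def name(self) -> str:
        return "A" + "".join(str(b) for b in self.membership)

    @property
    def size(self) -> int:
        return sum(self.membership)

    @property
    def mask(self) -> int:
        """Integer value of the membership vector, A1 as the most significant bit."""
        m = 0
        for b in self.membership:
            m = (m << 1) | b
        return m

    @property
    def assays(self) -> frozenset[int]:
        """1-based indices of the included assays."""
        return frozenset(i + 1 for i, b in enumerate(self.membership) if b)

    def contains(self, other: "SubsetModel") -> bool:
        """True iff every assay of ``other`` is included in this model."""
        return (other.mask & ~self.mask) == 0

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def parse_model_name(name: str) -> SubsetModel:
    """Parse a nomenclature string such as ``"A10000000001111"``.

    Raises
    ------
    ModelNameError
        If the leading ``"A"`` is missing, the length is not 15, or any
        character is not ``'0'``/``'1'`` (the error names the offending
        position).
    """
    if not isinstance(name, str) or not name.startswith("A"):
        raise ModelNameError(f"model name must start with 'A': {name!r}")
    if len(name) != NUM_ASSAYS + 1:
        raise ModelNameError(
            f"model name must be 'A' + {NUM_ASSAYS} binary characters "
            f"(length {NUM_ASSAYS + 1}), got length {len(name)}: {name!r}"
        )
    bits = []
    for pos, ch in enumerate(name[1:], start=1):
        if ch not in "01":
            raise ModelNameError(f"non-binary character {ch!r} at assay position A{pos} in {name!r}")
        bits.append(int(ch))
    return SubsetModel(tuple(bits))


def format_model_name(model: SubsetModel) -> str:
    """Inverse of :func:`parse_model_name`."""
    return model.name


def enumerate_subset_models(min_size: int = 2, include_full: bool = True) -> list[SubsetModel]:
    """All subsets of the 14 assays with at least ``min_size`` assays.

    Models are returned in ascending order of their integer mask (A1 as the
    most significant bit), which coincides with lexicographic name order.
    With ``min_size=2`` there are 2^14 − 15 = 16,369 models including the
    full 14-assay model, or 16,368 with ``include_full=False``.
    """
    if not 2 <= min_size <= NUM_ASSAYS:
        raise ValueError(f"min_size must be in 2..{NUM_ASSAYS}, got {min_size}")
    full = (1 << NUM_ASSAYS) - 1
    models = []
    for mask in range(1 << NUM_ASSAYS):
        if mask == full and not include_full:
            continue
        if mask.bit_count() >= min_size:
            models.append(SubsetModel.from_mask(mask))
    return models


def pathway_assays(model: SubsetModel, mode: Mode, roster: AssayRoster | None = None) -> frozenset[int]:
    """Assays of ``model`` participating in the ``mode`` pathway.

    The subset model truncates the full pathway to the assays it contains:
    e.g. the agonist pathway of ``A10000000001111`` is {A1, A11}.
    """
    pathway = (roster or _DEFAULT_ROSTER).pathway(mode)
    return model.assays & pathway


def union_size(a: SubsetModel, b: SubsetModel) -> int:
    """Number of assays in the union of two models (battery size of the pair)."""
    return (a.mask | b.mask).bit_count()


def intersection_size(a: SubsetModel, b: SubsetModel) -> int:
    return (a.mask & b.mask).bit_count()


def hamming(a: SubsetModel, b: SubsetModel) -> int:
    """Number of assay positions where the two memberships differ."""
    return (a.mask ^ b.mask).bit_count()


_DEFAULT_ROSTER = default_roster()
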