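"""Lipid domain types: fatty acids, lipid classes, head groups and lipid objects.

The simulator models the yeast membrane lipidome with a small set of acyl
chains (C16:0, C16:1, C18:0, C18:1 plus the very-long-chain C26:0 reserved for
sphingolipids) and thirteen lipid classes.  Every lipid is an attribute-carrying
object: a class tag, a head group bound at the glycerol *sn3* position, an
ordered tuple of fatty-acid chains (*sn1* first) and a localization.  The
biochemical constraint that the *sn2* chain of a glycerolipid is unsaturated is
enforced at construction time and everywhere chains are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple


class FattyAcid(NamedTuple):
    """An acyl chain: carbon count and number of double bonds."""

    carbons: int
    double_bonds: int

    @property
    def unsaturated(self) -> bool:
        return self.double_bonds > 0

    def __str__(self) -> str:  # C18:1 style
        return f"C{self.carbons}:{self.double_bonds}"


C16_0 = FattyAcid(16, 0)
C16_1 = FattyAcid(16, 1)
C18_0 = FattyAcid(18, 0)
C18_1 = FattyAcid(18, 1)
C26_0 = FattyAcid(26, 0)

#: The four common acyl chains handled by the fatty-acid synthase, in canonical
#: order.  C26:0 is produced only within the lumped sphingolipid synthesis.
COMMON_FATTY_ACIDS: tuple[FattyAcid, ...] = (C16_0, C16_1, C18_0, C18_1)
UNSATURATED_FATTY_ACIDS: tuple[FattyAcid, ...] = (C16_1, C18_1)
ALLOWED_FATTY_ACIDS: frozenset[FattyAcid] = frozenset(COMMON_FATTY_ACIDS) | {C26_0}

#: Acetyl-CoA units consumed to build one chain (two carbons per unit,
#: initiation included); desaturation is folded into the synthesis draw.
ACETYL_PER_CHAIN: dict[FattyAcid, int] = {
    C16_0: 8, C16_1: 8, C18_0: 9, C18_1: 9, C26_0: 13,
}

#: Acetyl-CoA units consumed by the lumped ergosterol synthesis.
ACETYL_PER_ERGOSTEROL = 18


class LipidClass(str, Enum):
    PA = "PA"
    LYSO_PA = "lysoPA"
    CDP_DG = "CDP_DG"
    PS = "PS"
    PE = "PE"
    PC = "PC"
    PI = "PI"
    CL = "CL"
    DAG = "DAG"
    TAG = "TAG"
    ES = "ES"
    SE = "SE"
    SL = "SL"

    def __str__(self) -> str:
        return self.value


class Headgroup(str, Enum):
    PHOSPHATE = "phosphate"
    CDP = "CDP"
    SERINE = "serine"
    ETHANOLAMINE = "ethanolamine"
    CHOLINE = "choline"
    INOSITOL = "inositol"
    NONE = "none"


#: Head group implied by each lipid class.
HEADGROUP_BY_CLASS: dict[LipidClass, Headgroup] = {
    LipidClass.PA: Headgroup.PHOSPHATE,
    LipidClass.LYSO_PA: Headgroup.PHOSPHATE,
    LipidClass.CDP_DG: Headgroup.CDP,
    LipidClass.PS: Headgroup.SERINE,
    LipidClass.PE: Headgroup.ETHANOLAMINE,
    LipidClass.PC: Headgroup.CHOLINE,
    LipidClass.PI: Headgroup.INOSITOL,
    LipidClass.CL: Headgroup.PHOSPHATE,
    LipidClass.DAG: Headgroup.NONE,
    LipidClass.TAG: Headgroup.NONE,
    LipidClass.ES: Headgroup.NONE,
    LipidClass.SE: Headgroup.NONE,
    LipidClass.SL: Headgroup.INOSITOL,
}

#: Number of acyl chains carried by each class.
CHAIN_COUNT_BY_CLASS: dict[LipidClass, int] = {
    LipidClass.PA: 2,
    LipidClass.LYSO_PA: 1,
    LipidClass.CDP_DG: 2,
    LipidClass.PS: 2,
    LipidClass.PE: 2,
    LipidClass.PC: 2,
    LipidClass.PI: 2,
    LipidClass.CL: 4,
    LipidClass.DAG: 2,
    LipidClass.TAG: 3,
    LipidClass.ES: 0,
    LipidClass.SE: 1,
    LipidClass.SL: 1,
}

#: Glycerolipid classes whose position 2 (and, for cardiolipin, position 4 of
#: the second diacylglycerol half) must carry an unsaturated chain.
_SN2_POSITIONS: dict[LipidClass, tuple[int, ...]] = {
    LipidClass.PA: (1,),
    LipidClass.CDP_DG: (1,),
    LipidClass.PS: (1,),
    LipidClass.PE: (1,),
    LipidClass.PC: (1,),
    LipidClass.PI: (1,),
    LipidClass.DAG: (1,),
    LipidClass.TAG: (1,),
    LipidClass.CL: (1, 3),
}

#: The six phospholipid classes entering the ergosterol-to-phospholipid ratio.
PHOSPHOLIPID_CLASSES: tuple[LipidClass, ...] = (
    LipidClass.PA, LipidClass.PS, LipidClass.PE,
    LipidClass.PC, LipidClass.PI, LipidClass.CL,
)

#: The classes that occur in membranes (transport targets); intermediates
#: (lysoPA, CDP-DG) stay in the free pools until consumed.
MEMBRANE_CLASSES: tuple[LipidClass, ...] = (
    LipidClass.PA, LipidClass.PS, LipidClass.PE, LipidClass.PC, LipidClass.PI,
    LipidClass.CL, LipidClass.DAG, LipidClass.TAG, LipidClass.ES,
    LipidClass.SE, LipidClass.SL,
)


class Localization(str, Enum):
    FREE = "free"
    PLASMA = "plasma"
    SECRETORY_VESICLES = "secretory_vesicles"
    VACUOLE = "vacuole"
    NUCLEUS = "nucleus"
    PEROXISOME = "peroxisome"
    LIGHT_MICROSOMES = "light_microsomes"
    INNER_MITO = "inner_mito"
    OUTER_MITO = "outer_mito"
    LIPID_DROPLET = "lipid_droplet"


class LipidConstructionError(ValueError):
    """Raised when a lipid object would violate a structural invariant."""


def validate_chains(lipid_class: LipidClass, chains: tuple[FattyAcid, ...]) -> None:
    """Check chain count, sn2 unsaturation and C26:0 confinement for a class."""
    expected = CHAIN_COUNT_BY_CLASS[lipid_class]
    if len(chains) != expected:
        raise LipidConstructionError(
            f"{lipid_class} carries {expected} fatty acid(s), got {len(chains)}"
        )
    for fa in chains:
        if fa not in ALLOWED_FATTY_ACIDS:
            raise LipidConstructionError(f"unknown fatty acid {fa}")
        if fa == C26_0 and lipid_class is not LipidClass.SL:
            raise LipidConstructionError(
                "C26:0 occurs only in the sphingolipid/ceramide context"
            )
    for pos in _SN2_POSITIONS.get(lipid_class, ()):
        if not chains[pos].unsaturated:
            raise LipidConstructionError(
                f"{lipid_class} requires an unsaturated chain at sn2 "
                f"(position {pos}), got {chains[pos]}"
            )
    if lipid_class is LipidClass.SL and chains != (C26_0,):
        raise LipidConstructionError("SL carries exactly one C26:0 chain")


@dataclass(frozen=True)
class Lipid:
    """An individual lipid molecule.

    Instances are immutable; reactions produce transformed copies.  Within the
    simulation state, lipids of identical (class, chains) are exchangeable and
    are therefore stored as tallies; `Lipid` objects are materialized at the
    API boundary.
    """

    lipid_class: LipidClass
    fatty_acids: tuple[FattyAcid, ...] = ()
    headgroup: Headgroup = field(default=None)  # type: ignore[assignment]
    localization: Localization = Localization.FREE

    def __post_init__(self) -> None:
        if self.headgroup is None:
            object.__setattr__(self, "headgroup", HEADGROUP_BY_CLASS[self.lipid_class])
        validate_chains(self.lipid_class, tuple(self.fatty_acids))
        if self.headgroup is not HEADGROUP_BY_CLASS[self.lipid_class]:
            raise LipidConstructionError(
                f"{self.lipid_class} carries head group "
                f"{HEADGROUP_BY_CLASS[self.lipid_class].value}, "
                f"got {self.headgroup.value}"
            )


def make_lipid(
    lipid_class: LipidClass | str,
    fatty_acids: tuple[FattyAcid, ...] | list[FattyAcid] = (),
    headgroup: Headgroup | str | None = None,
) -> Lipid:
    """Construct a validated free lipid object.

    Raises
    ------
    LipidConstructionError
        If the chain count does not match the class, a glycerolipid sn2
        position is saturated, C26:0 appears outside a sphingolipid, or the
        head group does not match the class.
    """
    lipid_class = LipidClass(lipid_class)
    if headgroup is not None:
        headgroup = Headgroup(headgroup)
    return Lipid(lipid_class, tuple(fatty_acids), headgroup)


# ---------------------------------------------------------------------------
# Chain-composition spaces
#
# The state stores, per lipid class, an integer count vector over the class's
# enumerated chain compositions.  Enumeration order is the lexicographic
# product of per-position choices: sn1-type positions range over the four
# common chains, sn2-type positions over the two unsaturated ones.
# ---------------------------------------------------------------------------

_SN1_CHOICES = COMMON_FATTY_ACIDS
_SN2_CHOICES = UNSATURATED_FATTY_ACIDS


def _product_space(*positions: tuple[FattyAcid, ...]) -> tuple[tuple[FattyAcid, ...], ...]:
    space: list[tuple[FattyAcid, ...]] = [()]
    for choices in positions:
        space = [prefix + (fa,) for prefix in space for fa in choices]
    return tuple(space)


#: Per-class enumeration of all admissible chain compositions.
CHAIN_SPACE: dict[LipidClass, tuple[tuple[FattyAcid, ...], ...]] = {
    LipidClass.LYSO_PA: _product_space(_SN1_CHOICES),
    LipidClass.PA: _product_space(_SN1_CHOICES, _SN2_CHOICES),
    LipidClass.CDP_DG: _product_space(_SN1_CHOICES, _SN2_CHOICES),
    LipidClass.PS: _product_space(_SN1_CHOICES, _SN2_CHOICES),
    LipidClass.PE: _product_space(_SN1_CHOICES, _SN2_CHOICES),
    LipidClass.PC: _product_space(_SN1_CHOICES, _SN2_CHOICES),
    LipidClass.PI: _product_space(_SN1_CHOICES, _SN2_CHOICES),
    LipidClass.DAG: _product_space(_SN1_CHOICES, _SN2_CHOICES),
    LipidClass.TAG: _product_space(_SN1_CHOICES, _SN2_CHOICES, _SN1_CHOICES),
    LipidClass.CL: _product_space(_SN1_CHOICES, _SN2_CHOICES, _SN1_CHOICES, _SN2_CHOICES),
    LipidClass.ES: ((),),
    LipidClass.SE: _product_space(_SN1_CHOICES),
    LipidClass.SL: ((C26_0,),),
}

CHAIN_INDEX: dict[LipidClass, dict[tuple[FattyAcid, ...], int]] = {
    cls: {chains: i for i, chains in enumerate(space)}
    for cls, space in CHAIN_SPACE.items()
}

#: Number of admissible compositions per class.
SPACE_SIZE: dict[LipidClass, int] = {c: len(s) for c, s in CHAIN_SPACE.items()}

#: Per-class matrix (n_comps x 5) counting chains of each species
#: (C16:0, C16:1, C18:0, C18:1, C26:0) in every composition.
ALL_FATTY_ACIDS: tuple[FattyAcid, ...] = COMMON_FATTY_ACIDS + (C26_0,)


def chain_species_matrix(lipid_class: LipidClass):
    import numpy as np

    space = CHAIN_SPACE[lipid_class]
    mat = np.zeros((len(space), len(ALL_FATTY_ACIDS)), dtype=np.int64)
    index = {fa: j for j, fa in enumerate(ALL_FATTY_ACIDS)}
    for i, chains in enumerate(space):
        for fa in chains:
            mat[i, index[fa]] += 1
    return mat
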