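"""Design of a copy-balanced 16S mock community.

A mock community mixes genomic DNA from organisms with known genomes so
that sequencing output can be compared against a known truth.  Because
genomes differ both in size (hence in genome copies per microgram of
DNA) and in 16S rRNA gene copy number, equal *masses* of DNA do not give
equal 16S representation.  This module computes, for each member, the
mass of genomic DNA required so that every member contributes the same
number of 16S rRNA gene copies to the pooled stock:

    mass_ug = target_copies / (n_16s_copies * copies_per_ug)

where ``copies_per_ug`` follows the standard double-stranded DNA
molarity formula with a mean molar mass of 650 g/mol per base pair.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "AVOGADRO",
    "MEAN_BP_MASS_G_PER_MOL",
    "MockMember",
    "MockRecipe",
    "copies_per_microgram",
    "mass_for_target_copies",
    "design_equal_mock",
    "load_members",
    "packaged_members",
    "recipe_frame",
]

AVOGADRO = 6.022e23
#: mean molar mass of one double-stranded base pair, g/mol
MEAN_BP_MASS_G_PER_MOL = 650.0


def copies_per_microgram(genome_size: int) -> float:
    """Genome copies contained in one microgram of double-stranded DNA.

    Parameters
    ----------
    genome_size : int
        Genome length in base pairs; must be positive.

    Returns
    -------
    float
        ``1e-6 g * N_A / (genome_size * 650 g/mol/bp)``, i.e. about
        ``9.2646e14 / genome_size``.
    """
    if genome_size <= 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    return 1e-6 * AVOGADRO / (genome_size * MEAN_BP_MASS_G_PER_MOL)


@dataclass(frozen=True)
class MockMember:
    """One organism in the mock community."""

    name: str
    genome_size: int
    n_16s_copies: int
    is_bacterial: bool = True
    genus: str = ""

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError(f"{self.name}: genome_size must be positive")
        if self.n_16s_copies < 1:
            raise ValueError(f"{self.name}: n_16s_copies must be >= 1")
        if not self.genus:
            object.__setattr__(self, "genus", self.name.split()[0])

    @property
    def copies_per_ug(self) -> float:
        """Genome copies per microgram of this member's DNA."""
        return copies_per_microgram(self.genome_size)


def mass_for_target_copies(member: MockMember, target_copies: float) -> float:
    """Micrograms of a member's genomic DNA holding ``target_copies`` 16S copies.

    Inverse of the balancing relation: one microgram of DNA carries
    ``n_16s_copies * copies_per_ug`` 16S gene copies.
    """
    if target_copies < 0:
        raise ValueError("target_copies must be non-negative")
    return target_copies / (member.n_16s_copies * member.copies_per_ug)


@dataclass
class MockRecipe:
    """Masses of member DNAs giving every member an equal 16S share."""

    members: list[MockMember]
    target_total_16s_copies: float
    per_member_target_copies: float
    per_member_mass: dict[str, float] = field(default_factory=dict)

    @property
    def fractions(self) -> dict[str, float]:
        """Each member's fractional 16S contribution (1 / member count)."""
        n = len(self.members)
        return {m.name: 1.0 / n for m in self.members}

    def realized_total_copies(self) -> float:
        """16S copies recovered from the masses; equals the target."""
        return sum(
            self.per_member_mass[m.name] * m.n_16s_copies * m.copies_per_ug
            for m in self.members
        )


def design_equal_mock(
    members: list[MockMember], target_total_16s_copies: float
) -> MockRecipe:
    """Compute DNA masses so each member contributes an equal 16S share.

    With *k* members, each contributes ``target_total / k`` copies
    (5 % each for a 20-member community).
    """
    if not members:
        raise ValueError("member list is empty")
    if target_total_16s_copies <= 0:
        raise ValueError("target_total_16s_copies must be positive")
    per = target_total_16s_copies / len(members)
    masses = {m.name: mass_for_target_copies(m, per) for m in members}
    return MockRecipe(
        members=list(members),
        target_total_16s_copies=target_total_16s_copies,
        per_member_target_copies=per,
        per_member_mass=masses,
    )


def load_members(path) -> list[MockMember]:
    """Read a member design table (TSV: name, genome_size_bp, n_16s_copies, is_bacterial)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "genome_size_bp", "n_16s_copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    members = []
    for row in df.itertuples(index=False):
        members.append(
            MockMember(
                name=str(row.name),
                genome_size=int(row.genome_size_bp),
                n_16s_copies=int(row.n_16s_copies),
                is_bacterial=bool(getattr(row, "is_bacterial", True)),
                genus=str(getattr(row, "genus", "")) if hasattr(row, "genus") else "",
            )
        )
    return members


def packaged_members(with_reported: bool = False):
    """The bundled 20-member community design table (19 bacteria, 1 archaeon).

    Genome sizes and per-genome 16S copy numbers are literature values for
    the strains listed; ``copies_per_ug_reported`` holds the published
    per-microgram estimates at three significant figures, kept for
    regression-testing the calculator.  The archaeon is a control for
    non-specific amplification and is excluded from bacterial summaries
    downstream.
    """
    ref = importlib.resources.files("mockamp") / "data" / "mock_members.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
        members = load_members(path)
    if with_reported:
        return members, dict(zip(df["name"], df["copies_per_ug_reported"]))
    return members


def recipe_frame(recipe: MockRecipe) -> pd.DataFrame:
    """Recipe as a table: one row per member with copies/µg, target copies and mass."""
    rows = []
    for m in recipe.members:
        rows.append(
            {
                "name": m.name,
                "genus": m.genus,
                "genome_size_bp": m.genome_size,
                "n_16s_copies": m.n_16s_copies,
                "is_bacterial": int(m.is_bacterial),
                "copies_per_ug": m.copies_per_ug,
                "target_copies": recipe.per_member_target_copies,
                "mass_ug": recipe.per_member_mass[m.name],
            }
        )
    return pd.DataFrame(rows)
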