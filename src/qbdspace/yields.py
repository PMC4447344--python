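"""CQA computation from raw extract measurements.

A run's CQAs are yields: the amount of dry matter or of an active
ingredient recovered in the pooled extract per gram of basis material,

    yield = content_in_extract (mg/g extract) * extract_mass (g) / basis_mass (g)

in mg per g of basis.  The basis differs per CQA: phenolic-acid yields are
reported per gram of Danshen, hydroxysafflor yellow A per gram of Honghua,
and dry matter per gram of total plant material.  The design-table fixture
already stores yields, so this module is only needed when starting from
raw content/mass measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ExtractMeasurement", "dry_matter_yield", "ingredient_yield"]


@dataclass(frozen=True)
class ExtractMeasurement:
    """Raw measurements of one pooled extract.

    Contents are in mg per g of extract; masses in g.  ``basis_masses``
    maps basis names (e.g. ``Danshen``, ``Honghua``, ``Material``) to the
    charged material masses; ``ingredient_basis`` maps each ingredient to
    its basis name.
    """

    dry_matter_content: float
    extract_mass: float
    material_mass: float
    ingredient_contents: dict[str, float] = field(default_factory=dict)
    basis_masses: dict[str, float] = field(default_factory=dict)
    ingredient_basis: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.extract_mass <= 0 or self.material_mass <= 0:
            raise ValueError("extract and material masses must be > 0")
        if self.dry_matter_content < 0:
            raise ValueError("dry matter content must be >= 0")
        for name, c in self.ingredient_contents.items():
            if c < 0:
                raise ValueError(f"content of {name!r} must be >= 0")
        for name, m in self.basis_masses.items():
            if m <= 0:
                raise ValueError(f"basis mass {name!r} must be > 0")


def dry_matter_yield(m: ExtractMeasurement) -> float:
    """Dry matter recovered per g of total material (mg/g)."""
    return m.dry_matter_content * m.extract_mass / m.material_mass


def ingredient_yield(m: ExtractMeasurement, ingredient: str) -> float:
    """Ingredient recovered per g of its basis material (mg/g basis).

    The basis mass is looked up through ``ingredient_basis`` when present,
    falling back to the total material mass.
    """
    try:
        content = m.ingredient_contents[ingredient]
    except KeyError:
        raise KeyError(
            f"unknown ingredient {ingredient!r}; measured: "
            f"{sorted(m.ingredient_contents)}"
        ) from None
    basis_name = m.ingredient_basis.get(ingredient)
    if basis_name is None:
        basis = m.material_mass
    else:
        try:
            basis = m.basis_masses[basis_name]
        except KeyError:
            raise KeyError(
                f"no basis mass recorded for {basis_name!r} "
                f"(needed by {ingredient!r})"
            ) from None
    return content * m.extract_mass / basis
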