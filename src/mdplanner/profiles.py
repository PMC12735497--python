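"""Family profiles and adult energy requirements (BMI, BMR, DER).

The adult recommender scores candidate days against the user's Daily Energy
Requirement, DER = BMR x PAL, with the Physical Activity Level one of five
fixed multipliers.  BMR comes from the Mifflin-St Jeor equation; the choice
is isolated behind :func:`compute_bmr` so an alternative (e.g.
Harris-Benedict) can be swapped in one place.  Child plans are rule-based
with fixed age-group portions, so no child energy computation exists here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .model import COUNTRIES, ModelError

__all__ = [
    "PAL_LEVELS",
    "CHILD_AGE_GROUPS",
    "AdultProfile",
    "ChildProfile",
    "Family",
    "EnergyRequirements",
    "compute_bmi",
    "compute_bmr",
    "compute_der",
    "energy_requirements",
    "load_profiles",
    "write_profiles",
]

#: The five physical-activity multipliers, sedentary through extra active.
PAL_LEVELS: tuple[float, ...] = (1.2, 1.375, 1.55, 1.725, 1.9)

CHILD_AGE_GROUPS: tuple[str, ...] = ("3-6", "7-12", "13-15", "16-18")


@dataclass(frozen=True)
class AdultProfile:
    name: str
    sex: str  # male | female
    birth_year: int
    height_m: float
    weight_kg: float
    pal: float
    milk_allergy: bool = False
    country: str = "Spain"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ModelError(f"profile {self.name!r}: sex must be male or female")
        if not 0.5 < self.height_m < 2.5:
            raise ModelError(f"profile {self.name!r}: implausible height {self.height_m}")
        if not 20 < self.weight_kg < 300:
            raise ModelError(f"profile {self.name!r}: implausible weight {self.weight_kg}")
        if self.pal not in PAL_LEVELS:
            raise ModelError(
                f"profile {self.name!r}: PAL {self.pal} not in {PAL_LEVELS}"
            )
        if self.country not in COUNTRIES:
            raise ModelError(f"profile {self.name!r}: unknown country {self.country!r}")


@dataclass(frozen=True)
class ChildProfile:
    name: str
    age_group: str
    school: str | None = None
    school_lunch: bool = False
    milk_allergy: bool = False
    snack: bool = False
    country: str = "Spain"

    def __post_init__(self) -> None:
        if self.age_group not in CHILD_AGE_GROUPS:
            raise ModelError(
                f"child {self.name!r}: age group must be one of {CHILD_AGE_GROUPS}"
            )
        if self.school_lunch and not self.school:
            raise ModelError(
                f"child {self.name!r}: school_lunch requires a school name"
            )
        if self.country not in COUNTRIES:
            raise ModelError(f"child {self.name!r}: unknown country {self.country!r}")


@dataclass(frozen=True)
class Family:
    name: str
    adults: tuple[AdultProfile, ...]
    children: tuple[ChildProfile, ...]


@dataclass(frozen=True)
class EnergyRequirements:
    age: int
    bmi: float
    bmr: float
    der: float


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body Mass Index, kg/m^2."""
    if weight_kg <= 0 or height_m <= 0:
        raise ModelError("BMI needs positive weight and height")
    return weight_kg / height_m**2


def compute_bmr(profile: AdultProfile, reference_year: int) -> float:
    """Basal Metabolic Rate (kcal/day), Mifflin-St Jeor.

    10*weight(kg) + 6.25*height(cm) - 5*age + (+5 male / -161 female).
    Age is reference_year - birth_year (profiles record only a birth year).
    Adults only: age must be >= 18.
    """
    age = reference_year - profile.birth_year
    if age < 18:
        raise ModelError(
            f"profile {profile.name!r}: age {age} < 18; the adult recommender "
            "does not compute child energy needs"
        )
    sex_term = 5.0 if profile.sex == "male" else -161.0
    return (
        10.0 * profile.weight_kg
        + 6.25 * (profile.height_m * 100.0)
        - 5.0 * age
        + sex_term
    )


def compute_der(bmr: float, pal: float) -> float:
    """Daily Energy Requirement (kcal/day) = BMR x PAL."""
    if pal not in PAL_LEVELS:
        raise ModelError(f"PAL {pal} is not one of the five listed levels")
    if bmr <= 0:
        raise ModelError("BMR must be positive")
    return bmr * pal


def energy_requirements(
    profile: AdultProfile, reference_year: int
) -> EnergyRequirements:
    bmr = compute_bmr(profile, reference_year)
    return EnergyRequirements(
        age=reference_year - profile.birth_year,
        bmi=compute_bmi(profile.weight_kg, profile.height_m),
        bmr=bmr,
        der=compute_der(bmr, profile.pal),
    )


# ---------------------------------------------------------------------------
# profiles.json

def load_profiles(path: str | Path) -> list[Family]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    families = []
    for fam in payload["families"]:
        adults = tuple(AdultProfile(**a) for a in fam.get("adults", []))
        children = tuple(ChildProfile(**c) for c in fam.get("children", []))
        families.append(Family(name=fam["name"], adults=adults, children=children))
    return families


def write_profiles(families: list[Family], path: str | Path) -> None:
    payload = {
        "families": [
            {
                "name": f.name,
                "adults": [vars(a) for a in f.adults],
                "children": [vars(c) for c in f.children],
            }
            for f in families
        ]
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
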