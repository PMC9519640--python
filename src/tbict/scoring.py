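"""Deterministic admission-CT severity scoring for traumatic brain injury.

Three systems are implemented, all computed from the same structured
description of a single admission CT (:class:`CTFindings`):

* **Marshall CT classification** — six classes: diffuse injury I–IV by
  cistern status and midline shift, and evacuated (V) / non-evacuated (VI)
  mass lesion for any high- or mixed-density lesion larger than 25 cm³.
* **Helsinki CT score** — an additive score in [−3, 14] built from lesion
  type (SDH +2, ICH/contusion +2, EDH −3), haematoma volume > 25 cm³ (+2),
  intraventricular haemorrhage (+3), and suprasellar cistern status
  (normal 0 / compressed +1 / obliterated +5).
* **NIRIS** (NeuroImaging Radiological Interpretation System, updated
  definitions) — ordinal categories 0–4; a patient receives the *highest*
  category whose criterion list is met.

Volumes refer to the largest single lesion of each type, in cm³, which is
the clinical measurement convention; thresholds are per lesion type, not
cumulative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

__all__ = [
    "CTFindings",
    "ScoreResult",
    "FindingsValidationError",
    "ScoringError",
    "helsinki_score",
    "marshall_class",
    "niris_category",
    "score_all",
    "MARSHALL_CLASSES",
    "SUPRASELLAR_STATES",
    "BASAL_STATES",
    "HYDROCEPHALUS_GRADES",
    "HERNIATION_GRADES",
]

MARSHALL_CLASSES = ("I", "II", "III", "IV", "V", "VI")
SUPRASELLAR_STATES = ("normal", "compressed", "obliterated")
BASAL_STATES = ("present", "compressed", "absent")
HYDROCEPHALUS_GRADES = ("none", "mild_moderate", "severe")
HERNIATION_GRADES = ("none", "focal", "diffuse")

HELSINKI_MIN = -3
HELSINKI_MAX = 14


class FindingsValidationError(ValueError):
    """Raised when a CTFindings value violates its invariants."""


class ScoringError(ValueError):
    """Raised when scoring a collection fails; carries per-record reasons."""

    def __init__(self, failures: Sequence[tuple[object, str]]):
        self.failures = list(failures)
        msg = "; ".join(f"record {rid!r}: {reason}" for rid, reason in self.failures)
        super().__init__(f"scoring failed for {len(self.failures)} record(s): {msg}")


@dataclass(frozen=True)
class CTFindings:
    """Structured radiological findings of one admission CT.

    All volumes are the volume of the *largest* lesion of that type in cm³
    (0 = absent); midline shift is in mm. Enumerated fields take lowercase
    string values from the module-level tuples. The default-constructed
    value is the "all-normal" CT (no visible intracranial pathology).
    """

    edh_volume_cm3: float = 0.0
    sdh_volume_cm3: float = 0.0
    ich_contusion_volume_cm3: float = 0.0
    sah_present: bool = False
    ivh_present: bool = False
    dai_present: bool = False
    skull_fracture: bool = False
    pneumocephalus: bool = False
    suprasellar_cisterns: str = "normal"
    basal_cisterns: str = "present"
    midline_shift_mm: float = 0.0
    hydrocephalus: str = "none"
    herniation: str = "none"
    duret_hemorrhage: bool = False
    mass_lesion_evacuated: bool = False

    def __post_init__(self) -> None:
        for name in ("edh_volume_cm3", "sdh_volume_cm3",
                     "ich_contusion_volume_cm3", "midline_shift_mm"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise FindingsValidationError(f"{name} must be numeric, got {v!r}")
            if not math.isfinite(v) or v < 0:
                raise FindingsValidationError(
                    f"{name} must be finite and non-negative, got {v!r}")
        _check_enum(self.suprasellar_cisterns, SUPRASELLAR_STATES, "suprasellar_cisterns")
        _check_enum(self.basal_cisterns, BASAL_STATES, "basal_cisterns")
        _check_enum(self.hydrocephalus, HYDROCEPHALUS_GRADES, "hydrocephalus")
        _check_enum(self.herniation, HERNIATION_GRADES, "herniation")
        for name in ("sah_present", "ivh_present", "dai_present", "skull_fracture",
                     "pneumocephalus", "duret_hemorrhage", "mass_lesion_evacuated"):
            v = getattr(self, name)
            if not isinstance(v, (bool,)) and v not in (0, 1):
                raise FindingsValidationError(f"{name} must be boolean, got {v!r}")

    @property
    def max_lesion_volume_cm3(self) -> float:
        return max(self.edh_volume_cm3, self.sdh_volume_cm3,
                   self.ich_contusion_volume_cm3)

    def has_visible_pathology(self) -> bool:
        """Any visible intracranial abnormality (Marshall class I is defined
        by its absence)."""
        return (
            self.max_lesion_volume_cm3 > 0
            or self.sah_present or self.ivh_present or self.dai_present
            or self.skull_fracture or self.pneumocephalus
            or self.duret_hemorrhage
            or self.midline_shift_mm > 0
            or self.suprasellar_cisterns != "normal"
            or self.basal_cisterns != "present"
            or self.hydrocephalus != "none"
            or self.herniation != "none"
        )


def _check_enum(value: str, allowed: tuple[str, ...], name: str) -> None:
    if value not in allowed:
        raise FindingsValidationError(
            f"{name} must be one of {allowed}, got {value!r}")


@dataclass(frozen=True)
class ScoreResult:
    """The three CT-system outputs for one patient."""

    marshall: str
    helsinki: int
    niris: int

    def __post_init__(self) -> None:
        if self.marshall not in MARSHALL_CLASSES:
            raise ValueError(f"invalid Marshall class {self.marshall!r}")
        if not HELSINKI_MIN <= self.helsinki <= HELSINKI_MAX:
            raise ValueError(f"Helsinki score {self.helsinki} outside "
                             f"[{HELSINKI_MIN}, {HELSINKI_MAX}]")
        if self.niris not in (0, 1, 2, 3, 4):
            raise ValueError(f"invalid NIRIS category {self.niris!r}")


# ---------------------------------------------------------------------------
# Helsinki CT score
# ---------------------------------------------------------------------------

def helsinki_score(findings: CTFindings) -> int:
    """Additive Helsinki CT score in [−3, 14].

    Components: SDH present +2; ICH/contusion present +2; EDH present −3;
    largest haematoma volume > 25 cm³ +2; IVH +3; suprasellar cisterns
    normal 0 / compressed +1 / obliterated +5. Lesion-type points are
    additive across coexisting lesion types.
    """
    score = 0
    if findings.sdh_volume_cm3 > 0:
        score += 2
    if findings.ich_contusion_volume_cm3 > 0:
        score += 2
    if findings.edh_volume_cm3 > 0:
        score -= 3
    if findings.max_lesion_volume_cm3 > 25:
        score += 2
    if findings.ivh_present:
        score += 3
    score += {"normal": 0, "compressed": 1, "obliterated": 5}[
        findings.suprasellar_cisterns]
    assert HELSINKI_MIN <= score <= HELSINKI_MAX
    return score


# ---------------------------------------------------------------------------
# Marshall CT classification
# ---------------------------------------------------------------------------

def marshall_class(findings: CTFindings) -> str:
    """Marshall class I–VI.

    Any high- or mixed-density lesion > 25 cm³ dominates the diffuse
    classes: V when surgically evacuated, VI otherwise. Otherwise midline
    shift > 5 mm gives IV; compressed/absent basal cisterns give III; any
    visible pathology gives II; a normal CT gives I.
    """
    if findings.max_lesion_volume_cm3 > 25:
        return "V" if findings.mass_lesion_evacuated else "VI"
    if findings.midline_shift_mm > 5:
        return "IV"
    if findings.basal_cisterns in ("compressed", "absent"):
        return "III"
    if findings.has_visible_pathology():
        return "II"
    return "I"


# ---------------------------------------------------------------------------
# NIRIS (updated definitions)
# ---------------------------------------------------------------------------

def niris_category(findings: CTFindings) -> int:
    """NIRIS ordinal category 0–4: the highest category whose criteria are met.

    Category 4: EDH/ICH/contusion > 20 cm³, SDH > 200 cm³, severe
    hydrocephalus, midline shift > 10 mm, diffuse herniation, or Duret
    haemorrhage. Category 3: EDH/ICH/contusion > 15 cm³, SDH > 50 cm³,
    shift > 5 mm, or focal herniation. Category 2: any lesion ≥ 0.5 cm³,
    DAI, IVH, mild/moderate hydrocephalus, or shift in (0, 5] mm.
    Category 1: skull fracture, pneumocephalus, any lesion in (0, 0.5) cm³,
    or SAH. Category 0: no abnormal finding.

    The 0.5 cm³ boundary is assigned to category 2 and midline-shift bands
    are half-open ((0,5] → 2, (5,10] → 3, > 10 → 4) so the criteria
    partition the axis.
    """
    edh = findings.edh_volume_cm3
    sdh = findings.sdh_volume_cm3
    ich = findings.ich_contusion_volume_cm3
    shift = findings.midline_shift_mm
    non_sdh_max = max(edh, ich)

    if (non_sdh_max > 20 or sdh > 200 or findings.hydrocephalus == "severe"
            or shift > 10 or findings.herniation == "diffuse"
            or findings.duret_hemorrhage):
        return 4
    if non_sdh_max > 15 or sdh > 50 or shift > 5 or findings.herniation == "focal":
        return 3
    if (max(edh, sdh, ich) >= 0.5 or findings.dai_present or findings.ivh_present
            or findings.hydrocephalus == "mild_moderate" or 0 < shift <= 5):
        return 2
    if (findings.skull_fracture or findings.pneumocephalus
            or 0 < max(edh, sdh, ich) < 0.5 or findings.sah_present):
        return 1
    return 0


# ---------------------------------------------------------------------------
# Batch scoring
# ---------------------------------------------------------------------------

def score_findings(findings: CTFindings) -> ScoreResult:
    """All three systems for a single CT."""
    return ScoreResult(marshall=marshall_class(findings),
                       helsinki=helsinki_score(findings),
                       niris=niris_category(findings))


def score_all(records: Iterable) -> list[ScoreResult]:
    """Element-wise scoring of patient records (anything with a ``findings``
    attribute, or bare CTFindings), order preserved.

    Per-record validation failures are aggregated into a single
    :class:`ScoringError` carrying record identifiers.
    """
    results: list[ScoreResult] = []
    failures: list[tuple[object, str]] = []
    for i, rec in enumerate(records):
        f = rec.findings if hasattr(rec, "findings") else rec
        rid = getattr(rec, "patient_id", i)
        try:
            if not isinstance(f, CTFindings):
                raise FindingsValidationError(
                    f"expected CTFindings, got {type(f).__name__}")
            results.append(score_findings(f))
        except (FindingsValidationError, ValueError) as exc:
            failures.append((rid, str(exc)))
    if failures:
        raise ScoringError(failures)
    return results


def enumerate_findings_lattice(
    volumes: Sequence[float] = (0.0, 0.3, 1.0, 16.0, 21.0, 26.0, 60.0, 201.0),
    shifts: Sequence[float] = (0.0, 3.0, 6.0, 12.0),
) -> Iterable[CTFindings]:
    """Discrete lattice over the findings space for brute-force checks.

    Yields every combination of the given per-lesion volume levels, shift
    levels, suprasellar-cistern states, IVH, evacuation and grouped
    "minor" (SAH/fracture/pneumocephalus/DAI, toggled jointly — they only
    gate NIRIS categories 1-2) and "mass-effect" findings (basal cisterns,
    hydrocephalus, herniation, Duret, stepped jointly through their
    severity grades). Grouping fields that never enter the same scoring
    criterion separately keeps the lattice near 1.5e5 combinations while
    still reaching every attainable score of all three systems.
    """
    import itertools

    mass_effect = (
        ("present", "none", "none", False),
        ("compressed", "mild_moderate", "focal", False),
        ("absent", "severe", "diffuse", True),
    )
    for (edh, sdh, ich, sup, shift, ivh, minor, (bas, hydro, hern, duret),
         evac) in itertools.product(
            volumes, volumes, volumes, SUPRASELLAR_STATES, shifts,
            (False, True), (False, True), mass_effect, (False, True)):
        yield CTFindings(
            edh_volume_cm3=edh, sdh_volume_cm3=sdh,
            ich_contusion_volume_cm3=ich,
            sah_present=minor, skull_fracture=minor, pneumocephalus=minor,
            dai_present=minor, ivh_present=ivh,
            suprasellar_cisterns=sup, basal_cisterns=bas,
            midline_shift_mm=shift, hydrocephalus=hydro, herniation=hern,
            duret_hemorrhage=duret, mass_lesion_evacuated=evac)
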