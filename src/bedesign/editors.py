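"""Base-editor profiles and the sgRNA rank score.

A base editor converts a substrate base (C for CBEs, A for ABEs) inside a
protospacer-position window 5' of an NGG PAM. Editing efficiency depends on
the editor, on the dinucleotide context (the base immediately 5' of the
target base), and on where in the protospacer the target base sits.

Each editable base receives a score

    S = E - DP - WP

where E is the editor's efficiency starting value, DP the dinucleotide
context penalty (E times a per-context penalty factor) and WP the editing
window penalty (E times a fixed factor, charged when the base lies in the
observed window but outside the peak window). A guide is ranked by the best
score over its editable bases. Scores may be negative.

Protospacer positions are 1-based; position 1 is the 5' PAM-distal end and
the PAM occupies positions 21-23.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

BASES = ("T", "C", "A", "G")


class OutOfWindowError(ValueError):
    """Target position lies outside the editor's observed (targetable) window."""


class NoEditableBaseError(ValueError):
    """A guide was scored with no editable base in the window."""


@dataclass(frozen=True)
class EditorProfile:
    """An editor's substrate chemistry, PAM, windows and scoring constants.

    Parameters
    ----------
    name
        Editor identifier, e.g. ``"evoBE4max"``.
    substrate_base, product_base
        The conversion the deaminase performs on the protospacer strand:
        C->T (CBE) or A->G (ABE).
    pam
        IUPAC pattern at protospacer positions 21-23 (default NGG).
    observed_window, peak_window
        Inclusive 1-based protospacer position ranges: any detectable
        activity vs. maximal activity (no window penalty).
    efficiency_E
        Starting score value E, in points.
    dinuc_penalty_factor
        Penalty factor in [0, 1] per preceding base (5' of the target).
    window_penalty_factor
        Factor in [0, 1] applied when editing outside the peak window.
    """

    name: str
    substrate_base: str
    product_base: str
    pam: str = "NGG"
    observed_window: tuple[int, int] = (4, 8)
    peak_window: tuple[int, int] = (4, 8)
    efficiency_E: int = 10
    dinuc_penalty_factor: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BASES}
    )
    window_penalty_factor: float = 0.8

    def __post_init__(self) -> None:
        if (self.substrate_base, self.product_base) not in {("C", "T"), ("A", "G")}:
            raise ValueError(
                "substrate/product must be C->T (CBE) or A->G (ABE), got "
                f"{self.substrate_base}->{self.product_base}"
            )
        lo, hi = self.observed_window
        plo, phi = self.peak_window
        if not (lo <= plo and phi <= hi):
            raise ValueError("peak_window must be contained in observed_window")
        if self.efficiency_E <= 0:
            raise ValueError("efficiency_E must be positive")
        for b in BASES:
            f = self.dinuc_penalty_factor[b]
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"dinucleotide penalty factor for {b} out of [0,1]")
        if not 0.0 <= self.window_penalty_factor <= 1.0:
            raise ValueError("window_penalty_factor out of [0,1]")

    @property
    def is_cbe(self) -> bool:
        return self.substrate_base == "C"

    def in_observed(self, position: int) -> bool:
        return self.observed_window[0] <= position <= self.observed_window[1]

    def in_peak(self, position: int) -> bool:
        return self.peak_window[0] <= position <= self.peak_window[1]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "substrate_base": self.substrate_base,
            "product_base": self.product_base,
            "pam": self.pam,
            "observed_window": list(self.observed_window),
            "peak_window": list(self.peak_window),
            "efficiency_E": self.efficiency_E,
            "dinuc_penalty_factor": dict(self.dinuc_penalty_factor),
            "window_penalty_factor": self.window_penalty_factor,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EditorProfile":
        return cls(
            name=d["name"],
            substrate_base=d["substrate_base"],
            product_base=d["product_base"],
            pam=d.get("pam", "NGG"),
            observed_window=tuple(d["observed_window"]),
            peak_window=tuple(d["peak_window"]),
            efficiency_E=d["efficiency_E"],
            dinuc_penalty_factor=dict(d["dinuc_penalty_factor"]),
            window_penalty_factor=d.get("window_penalty_factor", 0.8),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "EditorProfile":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class ScoreBreakdown:
    """Score components for one editable base.

    ``position`` is the 1-based protospacer position of the target base,
    ``preceding_base`` the base 5' of it (``None`` when unknown, which is
    charged the editor's worst-case dinucleotide penalty).
    """

    position: int
    preceding_base: str | None
    DP: float
    WP: float
    S: float


def builtin_profiles() -> dict[str, EditorProfile]:
    """The four built-in editors with their published scoring constants.

    BE4-Gam is markedly less efficient in vivo than the second-generation
    editors and starts at E = 5; ancBE4max, evoBE4max and ABE8e start at
    E = 10. Dinucleotide penalty factors encode each deaminase's context
    preference (e.g. rat-APOBEC1 CBEs strongly disfavour GC; evoBE4max
    disfavours AC; ABE8e is context-insensitive). Windows are the in vitro
    estimates: the broad observed range with the peak range inside it.
    """
    return {
        "BE4-Gam": EditorProfile(
            name="BE4-Gam",
            substrate_base="C",
            product_base="T",
            observed_window=(3, 10),
            peak_window=(4, 8),
            efficiency_E=5,
            dinuc_penalty_factor={"T": 0.0, "C": 0.4, "A": 0.6, "G": 0.8},
        ),
        "ancBE4max": EditorProfile(
            name="ancBE4max",
            substrate_base="C",
            product_base="T",
            observed_window=(3, 9),
            peak_window=(4, 7),
            efficiency_E=10,
            dinuc_penalty_factor={"T": 0.0, "C": 0.2, "A": 0.2, "G": 0.8},
        ),
        "evoBE4max": EditorProfile(
            name="evoBE4max",
            substrate_base="C",
            product_base="T",
            observed_window=(1, 11),
            peak_window=(4, 8),
            efficiency_E=10,
            dinuc_penalty_factor={"T": 0.0, "C": 0.2, "A": 0.8, "G": 0.2},
        ),
        "ABE8e": EditorProfile(
            name="ABE8e",
            substrate_base="A",
            product_base="G",
            observed_window=(3, 11),
            peak_window=(4, 8),
            efficiency_E=10,
            dinuc_penalty_factor={"T": 0.0, "C": 0.0, "A": 0.0, "G": 0.0},
        ),
    }


def dinucleotide_penalty(profile: EditorProfile, preceding_base: str | None) -> float:
    """Dinucleotide context penalty DP = E * PF[preceding base].

    ``preceding_base=None`` means the context is unknown (e.g. a bare
    20-mer with no 5' flank); the worst-case factor for the editor is
    charged so ranking stays conservative.
    """
    if preceding_base is None:
        factor = max(profile.dinuc_penalty_factor[b] for b in BASES)
    else:
        preceding_base = preceding_base.upper()
        if preceding_base not in profile.dinuc_penalty_factor:
            # ambiguous IUPAC base: context unknown, charge worst case
            factor = max(profile.dinuc_penalty_factor[b] for b in BASES)
        else:
            factor = profile.dinuc_penalty_factor[preceding_base]
    return profile.efficiency_E * factor


def window_penalty(profile: EditorProfile, position: int) -> float:
    """Window penalty WP: 0 in the peak window, E * 0.8 elsewhere in the
    observed window; positions outside the observed window are not
    targetable and raise :class:`OutOfWindowError`."""
    if not profile.in_observed(position):
        raise OutOfWindowError(
            f"position {position} outside {profile.name} observed window "
            f"{profile.observed_window[0]}-{profile.observed_window[1]}"
        )
    if profile.in_peak(position):
        return 0.0
    return profile.efficiency_E * profile.window_penalty_factor


def base_score(
    profile: EditorProfile, position: int, preceding_base: str | None
) -> ScoreBreakdown:
    """S = E - DP - WP for a single editable base (may be negative)."""
    dp = dinucleotide_penalty(profile, preceding_base)
    wp = window_penalty(profile, position)
    return ScoreBreakdown(
        position=position,
        preceding_base=preceding_base,
        DP=dp,
        WP=wp,
        S=profile.efficiency_E - dp - wp,
    )


def guide_score(
    profile: EditorProfile,
    editable_bases: Sequence[tuple[int, str | None]],
) -> tuple[ScoreBreakdown, int]:
    """Best score over a guide's editable bases.

    Returns the :class:`ScoreBreakdown` attaining the maximum S and its
    protospacer position; ties break toward the smaller (5'-most) position.
    """
    if not editable_bases:
        raise NoEditableBaseError("guide has no editable base in the window")
    best: ScoreBreakdown | None = None
    for position, preceding in editable_bases:
        bd = base_score(profile, position, preceding)
        if best is None or bd.S > best.S or (bd.S == best.S and bd.position < best.position):
            best = bd
    assert best is not None
    return best, best.position


def worst_case_context(profile: EditorProfile) -> str:
    """The preceding base with the largest penalty factor (ties: T,C,A,G order)."""
    return max(BASES, key=lambda b: profile.dinuc_penalty_factor[b])
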