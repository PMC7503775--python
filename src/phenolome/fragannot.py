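"""Neutral-loss arithmetic for flavonoid glycoconjugate MSn spectra.

In negative-ion MSn of flavonoid glycoconjugates, each fragmentation
step releases glycosyl or acyl residues as neutral fragments whose
nominal masses are diagnostic: 162 amu for a hexose, 146 for a
deoxyhexose (or a p-coumaroyl group - the classic ambiguity resolved
by elution order), 132 for a pentose, 176/192/206 for feruloyl,
hydroxyferuloyl and sinapoyl acyls, 44 for the CO2 of a malonyl group,
120/90 for cross-ring cleavages of C-glycosides, and so on.  The
terminal ion is the deprotonated aglycone; C-glycosides additionally
show the marker ion [Agly+(42-18)-H]- (aglycone + ketene - water,
i.e. +24 amu).

This module does the bookkeeping: predicting fragment m/z from residue
losses, decomposing observed mass differences into residue multisets,
and annotating whole precursor/fragment ladders.  Nominal integer
masses are used throughout, matching how such losses are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

__all__ = [
    "DEFAULT_RESIDUES",
    "DEFAULT_AGLYCONES",
    "MARKER_OFFSET",
    "predict_fragment",
    "decompose_loss",
    "marker_ion",
    "StepAnnotation",
    "AnnotationPath",
    "SpectrumAnnotation",
    "annotate_spectrum",
]

#: Nominal neutral-loss masses (amu) of common residues.
DEFAULT_RESIDUES: dict[str, int] = {
    "hexose": 162,
    "deoxyhexose": 146,
    "pentose": 132,
    "feruloyl": 176,
    "hydroxyferuloyl": 192,
    "sinapoyl": 206,
    "sinapic_acid": 224,
    "coumaroyl": 146,
    "malonyl_CO2": 44,
    "malonyl_ketene": 204,  # ketene (42) retained on a hexose (162)
    "ketene": 42,
    "water": 18,
    "C_glycoside_cross_ring": 120,
    "C_glycoside_cross_ring_minor": 90,
    "C_glycoside_full": 162,
}

#: Deprotonated nominal m/z of flavonoid aglycones, from molecular formulas.
DEFAULT_AGLYCONES: dict[str, int] = {
    "apigenin": 269,  # C15H10O5
    "luteolin": 285,  # C15H10O6
    "chrysoeriol": 299,  # C16H12O6
    "quercetin": 301,  # C15H10O7
    "naringenin": 271,  # C15H12O5
    "tricin": 329,  # C17H14O7
}

#: m/z offset of the C-glycoside marker ion [Agly+(42-18)-H]-.
MARKER_OFFSET = 42 - 18


def predict_fragment(
    precursor_mz: int,
    losses: list[str],
    residues: dict[str, int] | None = None,
) -> int:
    """Fragment m/z after sequential neutral losses of the named residues."""
    residues = DEFAULT_RESIDUES if residues is None else residues
    mz = int(precursor_mz)
    for name in losses:
        if name not in residues:
            raise KeyError(f"unknown residue {name!r}")
        mz -= residues[name]
    return mz


def decompose_loss(
    delta_mass: int,
    max_residues: int = 3,
    allowed_set: dict[str, int] | list[str] | None = None,
) -> list[tuple[str, ...]]:
    """All residue multisets (size <= ``max_residues``) summing to ``delta_mass``.

    Enumeration is a bounded depth-first search over residues in
    lexicographic name order, so the output order is deterministic:
    smaller multisets first, then lexicographic.  A zero delta yields
    the single empty multiset; an unexplainable delta yields an empty
    list.
    """
    if delta_mass < 0:
        raise ValueError("delta_mass must be >= 0")
    if max_residues < 1:
        raise ValueError("max_residues must be >= 1")
    if allowed_set is None:
        table = DEFAULT_RESIDUES
    elif isinstance(allowed_set, dict):
        table = allowed_set
    else:
        table = {name: DEFAULT_RESIDUES[name] for name in allowed_set}
    names = sorted(table)
    masses = [table[n] for n in names]
    min_mass = min(masses) if masses else 0

    results: list[tuple[str, ...]] = []
    stack: list[str] = []

    def dfs(remaining: int, start: int) -> None:
        if remaining == 0:
            results.append(tuple(stack))
            return
        if len(stack) == max_residues or remaining < min_mass:
            return
        for i in range(start, len(names)):
            if masses[i] <= remaining:
                stack.append(names[i])
                dfs(remaining - masses[i], i)
                stack.pop()

    dfs(int(delta_mass), 0)
    results.sort(key=lambda ms: (len(ms), ms))
    return results


def marker_ion(
    aglycone: str, library: dict[str, int] | None = None
) -> int:
    """m/z of the C-glycoside marker ion [Agly+(42-18)-H]-."""
    library = DEFAULT_AGLYCONES if library is None else library
    if aglycone not in library:
        raise KeyError(f"unknown aglycone {aglycone!r}")
    return library[aglycone] + MARKER_OFFSET


# ---------------------------------------------------------------------------
# spectrum annotation


@dataclass(frozen=True)
class StepAnnotation:
    """One fragmentation step: parent -> child with candidate losses."""

    parent_mz: int
    child_mz: int
    delta: int
    candidates: tuple[tuple[str, ...], ...]  # residue multisets, ranked

    @property
    def explained(self) -> bool:
        return len(self.candidates) > 0


@dataclass(frozen=True)
class AnnotationPath:
    """One consistent choice of residues along the whole ladder."""

    steps: tuple[tuple[str, ...], ...]

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(sorted(r for step in self.steps for r in step))

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.steps)


@dataclass
class SpectrumAnnotation:
    """Decomposition of a precursor/fragment ladder into residue losses."""

    precursor_mz: int
    fragments: tuple[int, ...]
    steps: list[StepAnnotation]
    paths: list[AnnotationPath] = field(default_factory=list)
    #: aglycone names whose [M-H]- matches the terminal fragment
    aglycone_matches: tuple[str, ...] = ()
    #: aglycone names matched via the [Agly+(42-18)-H]- marker ion
    marker_matches: tuple[str, ...] = ()

    @property
    def terminal_mz(self) -> int:
        return self.fragments[-1] if self.fragments else self.precursor_mz

    @property
    def fully_explained(self) -> bool:
        return all(s.explained for s in self.steps)


def annotate_spectrum(
    precursor_mz: int,
    fragments: list[int],
    allowed_set: dict[str, int] | list[str] | None = None,
    library: dict[str, int] | None = None,
    max_residues: int = 3,
) -> SpectrumAnnotation:
    """Annotate a fragmentation ladder by neutral-loss decomposition.

    ``fragments`` must be sorted descending and all below the
    precursor.  Each consecutive mass difference is decomposed into
    residue multisets; the terminal fragment is matched against the
    aglycone library both directly and through the +24 amu C-glycoside
    marker offset.  All consistent annotation paths are returned,
    ranked by fewest total residues, then lexicographically.  Steps
    with no decomposition are reported unexplained (and contribute no
    complete path), not raised as errors.
    """
    library = DEFAULT_AGLYCONES if library is None else library
    fragments = [int(f) for f in fragments]
    if any(f >= precursor_mz for f in fragments):
        raise ValueError("all fragments must be below the precursor m/z")
    if fragments != sorted(fragments, reverse=True):
        raise ValueError("fragments must be sorted descending")

    ladder = [int(precursor_mz)] + fragments
    steps = []
    for parent, child in zip(ladder[:-1], ladder[1:]):
        cands = decompose_loss(parent - child, max_residues, allowed_set)
        steps.append(
            StepAnnotation(
                parent_mz=parent,
                child_mz=child,
                delta=parent - child,
                candidates=tuple(cands),
            )
        )

    paths: list[AnnotationPath] = []
    if all(s.explained for s in steps):
        chosen: list[tuple[str, ...]] = []

        def walk(i: int) -> None:
            if i == len(steps):
                paths.append(AnnotationPath(tuple(chosen)))
                return
            for cand in steps[i].candidates:
                chosen.append(cand)
                walk(i + 1)
                chosen.pop()

        walk(0)
        paths.sort(key=lambda p: (p.n_residues, p.steps))

    terminal = ladder[-1]
    agly = tuple(sorted(n for n, mz in library.items() if mz == terminal))
    marker = tuple(
        sorted(n for n, mz in library.items() if mz + MARKER_OFFSET == terminal)
    )
    return SpectrumAnnotation(
        precursor_mz=int(precursor_mz),
        fragments=tuple(fragments),
        steps=steps,
        paths=paths,
        aglycone_matches=agly,
        marker_matches=marker,
    )


def brute_force_decompose(
    delta_mass: int,
    max_residues: int = 3,
    allowed_set: dict[str, int] | list[str] | None = None,
) -> list[tuple[str, ...]]:
    """Reference enumeration over the full multiset lattice (for checking)."""
    if allowed_set is None:
        table = DEFAULT_RESIDUES
    elif isinstance(allowed_set, dict):
        table = allowed_set
    else:
        table = {name: DEFAULT_RESIDUES[name] for name in allowed_set}
    names = sorted(table)
    out = []
    if delta_mass == 0:
        out.append(())
    for size in range(1, max_residues + 1):
        for combo in combinations_with_replacement(names, size):
            if sum(table[n] for n in combo) == delta_mass:
                out.append(combo)
    out.sort(key=lambda ms: (len(ms), ms))
    return out
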