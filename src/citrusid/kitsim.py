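"""Diagnostic kit assembly and chromatographic strip band simulation.

A kit multiplexes a cultivar-specific marker set with an rbcL
positive control (the chloroplast rbcL gene amplifies in every true
citrus sample, so a missing control band means the PCR itself failed).
Detection is on a four-line chromatographic strip: each amplicon's
single-stranded tag hybridises to its printed line and shows as a blue
band, so a kit holds at most three markers beside the control.  Kits
must also remain readable on a 2% agarose gel, hence a minimum pairwise
amplicon-size separation.

Diagnosis of a band pattern is three-way: ``invalid`` (no control band
— the run cannot be interpreted), ``target`` (control plus every marker
band), ``non_target`` (control present, at least one marker band
missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .genotype import GenotypeMatrix
from .markerselect import MarkerSet

C_PAS_LINES = 4
DEFAULT_MIN_SEPARATION = 30
DEFAULT_POSITIVE_CONTROL = "rbcL"

VERDICT_TARGET = "target"
VERDICT_NON_TARGET = "non_target"
VERDICT_INVALID = "invalid"


@dataclass(frozen=True)
class Kit:
    target: str
    positive_control: str
    members: tuple[str, ...]          # ordered by descending fragment size
    lines: Mapping[str, int]          # marker (incl. control) -> strip line
    fragment_sizes: Mapping[str, int]  # bp per marker incl. control

    @property
    def control_line(self) -> int:
        return self.lines[self.positive_control]

    @property
    def member_lines(self) -> dict[str, int]:
        return {m: self.lines[m] for m in self.members}


@dataclass(frozen=True)
class BandPattern:
    kit: Kit
    sample: str
    present_lines: frozenset[int]

    @property
    def band_count(self) -> int:
        return len(self.present_lines)


def design_kit(marker_set: MarkerSet,
               sizes: Mapping[str, int],
               min_separation: int = DEFAULT_MIN_SEPARATION,
               positive_control: str = DEFAULT_POSITIVE_CONTROL) -> Kit:
    """Assemble a strip kit from a unique marker set.

    ``sizes`` must give the amplicon size (bp) for every member and the
    positive control.  The control takes line 1; members take subsequent
    lines in descending amplicon size (larger fragments migrate less on
    a gel, so the ordering doubles as the gel lane reading order).
    Fails when the set is not unique, exceeds the strip's line capacity,
    or any two amplicons are closer than ``min_separation``.
    """
    if not marker_set.unique:
        raise ValueError(
            f"marker set for {marker_set.target!r} is not unique; "
            "a kit built from it could not identify the target")
    if len(marker_set.members) + 1 > C_PAS_LINES:
        raise ValueError(
            f"{len(marker_set.members)} markers plus control exceed the "
            f"{C_PAS_LINES}-line strip capacity")
    needed = (positive_control,) + tuple(marker_set.members)
    missing = [m for m in needed if m not in sizes]
    if missing:
        raise KeyError(f"no fragment size for {missing}")
    for i, a in enumerate(needed):
        for b in needed[i + 1:]:
            if abs(sizes[a] - sizes[b]) < min_separation:
                raise ValueError(
                    f"fragment sizes clash on gel: {a} ({sizes[a]} bp) vs "
                    f"{b} ({sizes[b]} bp) differ by < {min_separation} bp")
    ordered = tuple(sorted(marker_set.members,
                           key=lambda m: (-sizes[m], m)))
    lines = {positive_control: 1}
    for line, m in enumerate(ordered, start=2):
        lines[m] = line
    return Kit(target=marker_set.target,
               positive_control=positive_control,
               members=ordered,
               lines=lines,
               fragment_sizes={m: int(sizes[m]) for m in needed})


NO_TEMPLATE_CONTROL = "NC"


def predict_bands(kit: Kit, matrix: GenotypeMatrix, sample: str) -> BandPattern:
    """Band pattern the kit produces on a sample.

    ``sample`` is a cultivar of the matrix, or :data:`NO_TEMPLATE_CONTROL`
    for a no-template reaction (nothing amplifies, zero bands).
    """
    if sample == NO_TEMPLATE_CONTROL:
        return BandPattern(kit=kit, sample=sample, present_lines=frozenset())
    if sample not in matrix.data.index:
        raise KeyError(f"unknown sample {sample!r}")
    lines = {kit.control_line}
    for m in kit.members:
        if matrix.presence(sample, m) == 1:
            lines.add(kit.lines[m])
    return BandPattern(kit=kit, sample=sample, present_lines=frozenset(lines))


def diagnose(pattern: BandPattern, kit: Kit | None = None) -> str:
    """Three-way verdict from a band pattern (see module docstring)."""
    kit = pattern.kit if kit is None else kit
    if kit is not pattern.kit and kit != pattern.kit:
        raise ValueError("band pattern does not belong to this kit")
    if kit.control_line not in pattern.present_lines:
        return VERDICT_INVALID
    if all(line in pattern.present_lines for line in kit.member_lines.values()):
        return VERDICT_TARGET
    return VERDICT_NON_TARGET
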