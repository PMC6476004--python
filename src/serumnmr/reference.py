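"""Metabolite reference table: assignments, group effects, quantification windows.

The packaged table lists 23 serum metabolites with their 1H chemical shifts
and multiplicities, a relative baseline serum level, the direction and fold
change of each metabolite for the three pairwise group comparisons
(polyp vs control, CRC vs control, CRC vs polyp), and the subset of peaks
whose +-0.01 ppm windows do not overlap any other metabolite's signature
(used for window quantification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from .errors import ParseError

MULTIPLICITIES = ("s", "d", "t", "q", "m", "bra")
COMPARISONS = ("polyp_vs_control", "crc_vs_control", "crc_vs_polyp")
DIRECTIONS = ("up", "down", "none")

#: Group label -> comparison against control used to derive its mean level.
GROUPS = ("control", "polyp", "crc")


@dataclass(frozen=True)
class Peak:
    center: float  # ppm
    multiplicity: str
    weight: float  # fraction of the metabolite's total integral


@dataclass(frozen=True)
class Effect:
    direction: str  # up / down / none
    fold_change: float  # ratio >= 1; direction carries the sign


@dataclass(frozen=True)
class Metabolite:
    name: str
    peaks: tuple[Peak, ...]
    base_level: float
    effects: dict[str, Effect] = field(hash=False)
    quant_centers: tuple[float, ...] = ()

    def group_multiplier(self, group: str) -> float:
        """Mean concentration multiplier of `group` relative to control."""
        if group == "control":
            return 1.0
        comp = {"polyp": "polyp_vs_control", "crc": "crc_vs_control"}[group]
        eff = self.effects[comp]
        if eff.direction == "up":
            return eff.fold_change
        if eff.direction == "down":
            return 1.0 / eff.fold_change
        return 1.0


class MetaboliteReference:
    """Ordered collection of :class:`Metabolite` records."""

    def __init__(self, metabolites: list[Metabolite]):
        self._by_name = {m.name: m for m in metabolites}
        if len(self._by_name) != len(metabolites):
            raise ParseError("duplicate metabolite names in reference table")
        self.metabolites = list(metabolites)

    def __len__(self) -> int:
        return len(self.metabolites)

    def __iter__(self) -> Iterator[Metabolite]:
        return iter(self.metabolites)

    def __getitem__(self, name: str) -> Metabolite:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metabolites]


def _parse_peaks(text: str, row: str) -> tuple[Peak, ...]:
    peaks = []
    for part in text.split(";"):
        fields = part.split(":")
        if len(fields) != 3:
            raise ParseError(f"row {row!r}: malformed peak entry {part!r}")
        try:
            center = float(fields[0])
            weight = float(fields[2])
        except ValueError as exc:
            raise ParseError(f"row {row!r}: non-numeric peak field in {part!r}") from exc
        mult = fields[1]
        if mult not in MULTIPLICITIES:
            raise ParseError(f"row {row!r}: unknown multiplicity code {mult!r}")
        if not 0.0 <= center <= 9.0:
            raise ParseError(f"row {row!r}: peak center {center} outside [0, 9] ppm")
        if weight <= 0:
            raise ParseError(f"row {row!r}: nonpositive peak weight {weight}")
        peaks.append(Peak(center, mult, weight))
    total = sum(p.weight for p in peaks)
    if abs(total - 1.0) > 1e-6:
        raise ParseError(f"row {row!r}: peak weights sum to {total}, expected 1")
    # renormalize exactly so downstream integrals are well defined
    return tuple(Peak(p.center, p.multiplicity, p.weight / total) for p in peaks)


def _parse_effect(text: str, row: str) -> Effect:
    fields = text.split(":")
    if len(fields) != 2 or fields[0] not in DIRECTIONS:
        raise ParseError(f"row {row!r}: malformed effect entry {text!r}")
    try:
        fold = float(fields[1])
    except ValueError as exc:
        raise ParseError(f"row {row!r}: non-numeric fold change in {text!r}") from exc
    if fold < 1.0:
        raise ParseError(f"row {row!r}: fold change {fold} < 1 (direction carries sign)")
    return Effect(fields[0], fold)


def load_reference(path: str | Path | None = None) -> MetaboliteReference:
    """Load a metabolite reference table (the packaged one if `path` is None).

    Raises :class:`ParseError` for malformed rows, naming the offending row.
    """
    if path is None:
        source = resources.files("serumnmr.data") / "metabolite_reference.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()

    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError("reference table is empty")
    header = lines[0].split("\t")
    required = ["name", "peaks", "base_level", *COMPARISONS, "quant_peaks"]
    if header != required:
        raise ParseError(f"unexpected reference header {header!r}")

    metabolites = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(required):
            raise ParseError(f"row {cells[0]!r}: expected {len(required)} columns, got {len(cells)}")
        name = cells[0]
        if not name:
            raise ParseError("row with empty metabolite name")
        peaks = _parse_peaks(cells[1], name)
        try:
            base = float(cells[2])
        except ValueError as exc:
            raise ParseError(f"row {name!r}: non-numeric base level {cells[2]!r}") from exc
        if base <= 0:
            raise ParseError(f"row {name!r}: nonpositive base level {base}")
        effects = {comp: _parse_effect(cells[3 + i], name) for i, comp in enumerate(COMPARISONS)}
        try:
            quant = tuple(float(c) for c in cells[6].split(";") if c)
        except ValueError as exc:
            raise ParseError(f"row {name!r}: malformed quant peak list {cells[6]!r}") from exc
        if not quant:
            raise ParseError(f"row {name!r}: no quantification peaks listed")
        centers = {p.center for p in peaks}
        for c in quant:
            if c not in centers:
                raise ParseError(f"row {name!r}: quant peak {c} not among listed peaks")
        metabolites.append(Metabolite(name, peaks, base, effects, quant))

    return MetaboliteReference(metabolites)
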