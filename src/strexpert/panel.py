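"""Assay panel definition: loci, dye channels, allelic ladder, ILS, thresholds.

A panel bundles everything the caller needs to know about the chemistry:
which loci sit on which dye channel, the allelic-ladder composition used to
calibrate allele bins, the internal lane standard (ILS) used for size
calibration, and the interpretation thresholds. A PowerPlex-16-style
demonstration panel (16 loci on three dye channels plus an ILS dye, 210
ladder fragments in total) ships with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DyeChannel",
    "LocusDefinition",
    "ILSDefinition",
    "PanelDefinition",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "save_panel",
    "default_panel",
    "ladder_fragment_count",
]


class PanelFormatError(ValueError):
    """Raised when a panel file cannot be parsed into the documented schema."""


class PanelValidationError(ValueError):
    """Raised when a parsed panel violates a structural invariant."""


@dataclass(frozen=True)
class DyeChannel:
    """A fluorescent dye and its detector channel index in the trace."""

    name: str
    detector_index: int


@dataclass(frozen=True)
class LocusDefinition:
    """One STR locus: dye, repeat unit, ladder alleles, and stutter threshold.

    ``ladder_alleles`` is an ordered list of ``(designation, nominal size)``
    pairs. Microvariant designations (e.g. ``"9.3"``) are plain string labels
    carrying their own nominal size; no arithmetic is ever done on labels.
    """

    name: str
    dye: DyeChannel
    repeat_unit: int
    ladder_alleles: tuple[tuple[str, float], ...]
    stutter_threshold: float = 0.15
    is_codis: bool = False

    @property
    def designations(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.ladder_alleles)

    def size_of(self, designation: str) -> float:
        for a, s in self.ladder_alleles:
            if a == designation:
                return s
        raise KeyError(f"{designation!r} is not a ladder allele of {self.name}")

    @property
    def size_span(self) -> tuple[float, float]:
        sizes = [s for _, s in self.ladder_alleles]
        return min(sizes), max(sizes)


@dataclass(frozen=True)
class ILSDefinition:
    """Internal lane standard: one dye plus an ascending list of fragment sizes."""

    dye: DyeChannel
    fragment_sizes: tuple[float, ...]


@dataclass(frozen=True)
class PanelDefinition:
    loci: tuple[LocusDefinition, ...]
    ils: ILSDefinition
    analytical_threshold: float = 100.0
    phr_threshold: float = 0.5
    bin_half_width: float = 0.5
    sizing_range: tuple[float, float] = (100.0, 500.0)
    name: str = "panel"
    # Spectral calibration of the instrument; identity when None.
    crosstalk: np.ndarray | None = field(default=None, compare=False)

    @property
    def n_channels(self) -> int:
        idx = [l.dye.detector_index for l in self.loci] + [self.ils.dye.detector_index]
        return max(idx) + 1

    @property
    def dyes(self) -> tuple[DyeChannel, ...]:
        seen: dict[int, DyeChannel] = {}
        for loc in self.loci:
            seen.setdefault(loc.dye.detector_index, loc.dye)
        seen.setdefault(self.ils.dye.detector_index, self.ils.dye)
        return tuple(seen[i] for i in sorted(seen))

    def locus(self, name: str) -> LocusDefinition:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def crosstalk_matrix(self) -> np.ndarray:
        if self.crosstalk is None:
            return np.eye(self.n_channels)
        return np.asarray(self.crosstalk, dtype=float)

    def validate(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate locus name(s): {dup}")
        dye_idx = [d.detector_index for d in self.dyes]
        if len(set(dye_idx)) != len(dye_idx):
            raise PanelValidationError("dye detector_index values must be unique")
        for d in self.dyes:
            if not d.name:
                raise PanelValidationError("dye name must be non-empty")
        locus_dyes = {l.dye.detector_index for l in self.loci}
        if self.ils.dye.detector_index in locus_dyes:
            raise PanelValidationError("ILS dye must be distinct from locus dyes")
        lo, hi = self.sizing_range
        if not lo < hi:
            raise PanelValidationError("sizing_range min must be < max")
        for loc in self.loci:
            if loc.repeat_unit < 2:
                raise PanelValidationError(f"{loc.name}: repeat_unit must be >= 2")
            if not 0.0 <= loc.stutter_threshold <= 1.0:
                raise PanelValidationError(f"{loc.name}: stutter_threshold not in [0,1]")
            sizes = [s for _, s in loc.ladder_alleles]
            if not sizes:
                raise PanelValidationError(f"{loc.name}: empty ladder")
            if any(b <= a for a, b in zip(sizes, sizes[1:])):
                raise PanelValidationError(
                    f"{loc.name}: ladder allele sizes must be strictly increasing"
                )
            if min(sizes) < lo or max(sizes) > hi:
                raise PanelValidationError(
                    f"{loc.name}: ladder allele outside sizing_range {self.sizing_range}"
                )
        frs = self.ils.fragment_sizes
        if len(frs) < 4:
            raise PanelValidationError("ILS needs at least 4 fragments for calibration")
        if any(b <= a for a, b in zip(frs, frs[1:])):
            raise PanelValidationError("ILS fragment sizes must be strictly increasing")
        if not 0.0 <= self.phr_threshold <= 1.0:
            raise PanelValidationError("phr_threshold not in [0,1]")
        if self.crosstalk is not None:
            m = self.crosstalk_matrix()
            n = self.n_channels
            if m.shape != (n, n):
                raise PanelValidationError(f"crosstalk must be {n}x{n}")


def ladder_fragment_count(panel: PanelDefinition) -> int:
    """Total number of allelic-ladder fragments summed over all loci."""
    return sum(len(l.ladder_alleles) for l in panel.loci)


def _parse(doc: dict, origin: str) -> PanelDefinition:
    try:
        dyes = {d["name"]: DyeChannel(d["name"], int(d["detector_index"]))
                for d in doc["dyes"]}
        loci = []
        for entry in doc["loci"]:
            loci.append(LocusDefinition(
                name=entry["name"],
                dye=dyes[entry["dye"]],
                repeat_unit=int(entry["repeat_unit"]),
                ladder_alleles=tuple((str(a), float(s))
                                     for a, s in entry["ladder_alleles"]),
                stutter_threshold=float(entry.get("stutter_threshold", 0.15)),
                is_codis=bool(entry.get("is_codis", False)),
            ))
        ils = ILSDefinition(
            dye=dyes[doc["ils"]["dye"]],
            fragment_sizes=tuple(float(s) for s in doc["ils"]["fragment_sizes"]),
        )
        crosstalk = doc.get("crosstalk")
        panel = PanelDefinition(
            loci=tuple(loci),
            ils=ils,
            analytical_threshold=float(doc.get("analytical_threshold", 100.0)),
            phr_threshold=float(doc.get("phr_threshold", 0.5)),
            bin_half_width=float(doc.get("bin_half_width", 0.5)),
            sizing_range=tuple(float(x) for x in doc.get("sizing_range", (100, 500))),
            name=str(doc.get("name", "panel")),
            crosstalk=np.asarray(crosstalk, float) if crosstalk is not None else None,
        )
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise PanelFormatError(f"malformed panel file {origin}: {exc}") from exc
    panel.validate()
    return panel


def load_panel(path: str | Path) -> PanelDefinition:
    """Load and validate a panel from a JSON or YAML config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise PanelFormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise PanelFormatError(f"{path}: top level must be a mapping")
    return _parse(doc, str(path))


def save_panel(panel: PanelDefinition, path: str | Path) -> None:
    """Serialize a panel back to JSON/YAML; inverse of :func:`load_panel`."""
    doc = {
        "name": panel.name,
        "dyes": [{"name": d.name, "detector_index": d.detector_index}
                 for d in panel.dyes],
        "loci": [{
            "name": l.name,
            "dye": l.dye.name,
            "repeat_unit": l.repeat_unit,
            "ladder_alleles": [[a, s] for a, s in l.ladder_alleles],
            "stutter_threshold": l.stutter_threshold,
            "is_codis": l.is_codis,
        } for l in panel.loci],
        "ils": {"dye": panel.ils.dye.name,
                "fragment_sizes": list(panel.ils.fragment_sizes)},
        "analytical_threshold": panel.analytical_threshold,
        "phr_threshold": panel.phr_threshold,
        "bin_half_width": panel.bin_half_width,
        "sizing_range": list(panel.sizing_range),
    }
    if panel.crosstalk is not None:
        doc["crosstalk"] = panel.crosstalk_matrix().tolist()
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1) + "\n")


def default_panel() -> PanelDefinition:
    """The bundled PowerPlex-16-style demonstration panel (210 ladder fragments)."""
    ref = resources.files("strexpert.data").joinpath("pp16_panel.json")
    doc = json.loads(ref.read_text())
    return _parse(doc, "bundled pp16_panel.json")
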