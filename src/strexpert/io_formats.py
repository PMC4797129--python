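"""Standard artifact I/O: ABIF (.fsa) traces, CODIS CMF XML, CSV tables, PNG.

The ABIF dialect written here is deliberately minimal: version 101,
big-endian, channel data as 16-bit signed integers under DATA 1..n, dye
names under DyeN, sample name under SMPL, plus two custom string tags for
the run kind and panel id. ``read_fsa`` inverts ``write_fsa`` exactly on
quantized traces.

The CODIS export is a documented subset of the CMF 3.2 exchange format
(specimen / locus / allele elements, validated against the bundled XSD).
It contains only passing (unflagged) allele calls; flagged calls appear in
the allele table and the electropherogram plot instead.
"""

from __future__ import annotations

import struct
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle

from .calling import SampleProfile
from .simulate import Electropherogram

__all__ = [
    "AbifFormatError", "write_fsa", "read_fsa", "write_cmf",
    "write_allele_table", "read_allele_table", "write_plot",
    "load_status_grid",
]

_MAGIC = b"ABIF"
_VERSION = 101
_DIR_STRUCT = struct.Struct(">4sihhiiii")  # name, number, etype, esize, n, size, offset, handle
_HEADER_LEN = 128

_ET_SHORT = 4
_ET_PSTRING = 18
_ET_CSTRING = 19


class AbifFormatError(ValueError):
    """Raised on a malformed or truncated ABIF container."""


def _pstring(text: str) -> bytes:
    raw = text.encode("ascii", "replace")[:255]
    return bytes([len(raw)]) + raw


def _cstring(text: str) -> bytes:
    return text.encode("ascii", "replace") + b"\x00"


def write_fsa(trace: Electropherogram, path: str | Path) -> None:
    """Write a trace as a minimal ABIF v1.01 (.fsa) container.

    Channel values are rounded and clipped to the int16 range, as real CCD
    data are. Raises on an empty trace.
    """
    if trace.n_scans == 0 or trace.n_channels == 0:
        raise AbifFormatError("refusing to write a zero-length trace")
    entries: list[tuple[bytes, int, int, int, int, bytes]] = []

    def add(name: bytes, number: int, etype: int, esize: int, n: int, data: bytes):
        entries.append((name, number, etype, esize, n, data))

    values = np.clip(np.round(trace.values), -32768, 32767).astype(">i2")
    for c in range(trace.n_channels):
        add(b"DATA", c + 1, _ET_SHORT, 2, trace.n_scans, values[:, c].tobytes())
    dyes = trace.dye_names or tuple(f"DYE{c + 1}" for c in range(trace.n_channels))
    for c, dye in enumerate(dyes[: trace.n_channels]):
        p = _pstring(dye)
        add(b"DyeN", c + 1, _ET_PSTRING, 1, len(p), p)
    smpl = _pstring(trace.sample_id)
    add(b"SMPL", 1, _ET_PSTRING, 1, len(smpl), smpl)
    runk = _cstring(trace.run_kind)
    add(b"RunK", 1, _ET_CSTRING, 1, len(runk), runk)
    pani = _cstring(trace.panel_id)
    add(b"PanI", 1, _ET_CSTRING, 1, len(pani), pani)

    blob = bytearray()
    offset = _HEADER_LEN
    packed = []
    for name, number, etype, esize, n, data in entries:
        size = len(data)
        if size <= 4:
            inline = int.from_bytes(data.ljust(4, b"\x00"), "big", signed=True)
            packed.append(_DIR_STRUCT.pack(name, number, etype, esize, n,
                                           size, inline, 0))
        else:
            packed.append(_DIR_STRUCT.pack(name, number, etype, esize, n,
                                           size, offset + len(blob), 0))
            blob.extend(data)
    dir_offset = _HEADER_LEN + len(blob)
    header = bytearray(_HEADER_LEN)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    _DIR_STRUCT.pack_into(header, 6, b"tdir", 1, 1023, 28, len(entries),
                          28 * len(entries), dir_offset, 0)
    Path(path).write_bytes(bytes(header) + bytes(blob) + b"".join(packed))


def read_fsa(path: str | Path) -> Electropherogram:
    """Read an ABIF (.fsa) file back into an :class:`Electropherogram`."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_LEN or raw[0:4] != _MAGIC:
        raise AbifFormatError(f"{path}: not an ABIF file (bad magic)")
    (_, _, _, _, n_entries, _, dir_offset, _) = _DIR_STRUCT.unpack_from(raw, 6)
    end = dir_offset + 28 * n_entries
    if end > len(raw):
        raise AbifFormatError(f"{path}: truncated directory")

    channels: dict[int, np.ndarray] = {}
    dyes: dict[int, str] = {}
    sample_id, run_kind, panel_id = "sample", "sample", "panel"
    for k in range(n_entries):
        name, number, etype, _esize, n, size, offset, _h = _DIR_STRUCT.unpack_from(
            raw, dir_offset + 28 * k)
        if size <= 4:
            data = int(offset).to_bytes(4, "big", signed=True)[:size]
        else:
            if offset + size > len(raw):
                raise AbifFormatError(f"{path}: entry {name!r} overruns file")
            data = raw[offset:offset + size]
        if name == b"DATA":
            channels[number] = np.frombuffer(data, dtype=">i2", count=n).astype(float)
        elif name == b"DyeN":
            dyes[number] = data[1:1 + data[0]].decode("ascii", "replace")
        elif name == b"SMPL":
            sample_id = data[1:1 + data[0]].decode("ascii", "replace")
        elif name == b"RunK":
            run_kind = data.rstrip(b"\x00").decode("ascii", "replace")
        elif name == b"PanI":
            panel_id = data.rstrip(b"\x00").decode("ascii", "replace")
    if not channels:
        raise AbifFormatError(f"{path}: no DATA entries")
    order = sorted(channels)
    values = np.column_stack([channels[i] for i in order])
    dye_names = tuple(dyes.get(i, f"DYE{i}") for i in order)
    return Electropherogram(values=values, sample_id=sample_id,
                            panel_id=panel_id, run_kind=run_kind,
                            dye_names=dye_names)


def _cmf_schema() -> etree.XMLSchema:
    ref = resources.files("strexpert.data").joinpath("cmf_subset.xsd")
    with ref.open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def write_cmf(profile: SampleProfile, path: str | Path,
              kit: str = "PP16-like", validate: bool = True) -> None:
    """Write a CODIS CMF-subset XML document for one profile.

    Only unflagged (passing) calls are exported; loci with no passing call
    are omitted, and a fail-category profile yields a document with zero
    locus elements plus a status attribute.
    """
    root = etree.Element("CODISImportFile", Kit=kit)
    etree.SubElement(root, "HeaderVersion").text = "3.2-subset"
    spec = etree.SubElement(root, "SpecimenDetail",
                            ProfileCategory=profile.category)
    etree.SubElement(spec, "SpecimenID").text = profile.sample_id
    for name, res in profile.locus_results.items():
        passing = res.passing_calls
        if not passing:
            continue
        loc = etree.SubElement(spec, "Locus")
        etree.SubElement(loc, "LocusName").text = name
        etree.SubElement(loc, "Kit").text = kit
        for call in passing:
            al = etree.SubElement(loc, "Allele")
            etree.SubElement(al, "AlleleValue").text = call.designation
    doc = etree.ElementTree(root)
    if validate:
        _cmf_schema().assertValid(doc)
    doc.write(str(path), pretty_print=True, xml_declaration=True,
              encoding="UTF-8")


_TABLE_COLUMNS = ["sample", "locus", "allele", "size", "height", "flags"]


def write_allele_table(profiles: list[SampleProfile], path: str | Path) -> None:
    """Write every call (flagged included) of every profile as RFC-4180 CSV."""
    rows = []
    for prof in profiles:
        for res in prof.locus_results.values():
            for call in res.calls:
                rows.append({
                    "sample": prof.sample_id,
                    "locus": call.locus,
                    "allele": call.designation,
                    "size": round(call.size, 2),
                    "height": round(call.height, 1),
                    "flags": "|".join(sorted(call.flags)),
                })
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def read_allele_table(path: str | Path) -> pd.DataFrame:
    """Read an allele table back; inverse of :func:`write_allele_table`."""
    df = pd.read_csv(path, dtype={"allele": str, "flags": str},
                     keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_plot(trace: Electropherogram, path: str | Path, calls=None,
               calibration=None, title: str | None = None) -> None:
    """Render the electropherogram as a PNG, one panel per dye channel.

    When calls and a calibration are given, passing calls are marked with
    green triangles and flagged calls with red warning boxes, mirroring how
    review software distinguishes them.
    """
    n_ch = trace.n_channels
    fig = Figure(figsize=(11, 2.2 * n_ch), dpi=100)
    axes = fig.subplots(n_ch, 1, sharex=True)
    if n_ch == 1:
        axes = [axes]
    colors = ["tab:blue", "tab:green", "black", "tab:red"]
    x = np.arange(trace.n_scans)
    for c in range(n_ch):
        ax = axes[c]
        ax.plot(x, trace.values[:, c], lw=0.6,
                color=colors[c % len(colors)])
        dye = trace.dye_names[c] if c < len(trace.dye_names) else f"ch{c}"
        ax.set_ylabel(f"{dye}\nRFU", fontsize=8)
    if calls is not None and calibration is not None:
        for call in calls:
            scan = calibration.size_to_scan(call.size)
            # AlleleCall carries no channel; mark on the channel with the
            # tallest signal at this scan position
            i = min(max(int(round(scan)), 0), trace.n_scans - 1)
            ch = int(np.argmax(trace.values[i, :]))
            ax = axes[ch]
            if call.flags:
                h = max(call.height, 1.0)
                ax.add_patch(Rectangle((scan - 25, 0), 50, h * 1.1,
                                       fill=False, edgecolor="red", lw=1.2))
                ax.annotate(call.designation, (scan, h * 1.15), color="red",
                            ha="center", fontsize=7)
            else:
                ax.plot([scan], [call.height * 1.05], marker="v",
                        color="green", ms=4)
                ax.annotate(call.designation, (scan, call.height * 1.12),
                            color="green", ha="center", fontsize=7)
    axes[-1].set_xlabel("scan")
    fig.suptitle(title or f"{trace.sample_id} ({trace.run_kind})", fontsize=10)
    FigureCanvasAgg(fig).print_png(str(path))


def load_status_grid(path: str | Path) -> pd.DataFrame:
    """Load a reproducibility status grid (codes Y / Y* / F) from CSV.

    A leading ``replicate`` index column, if present, is dropped.
    """
    df = pd.read_csv(path, dtype=str)
    if "replicate" in df.columns:
        df = df.drop(columns=["replicate"])
    return df
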