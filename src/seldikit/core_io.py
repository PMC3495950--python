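"""Domain types and readers/writers for TOF spectra, plus replicate averaging.

A :class:`Spectrum` is a pair of aligned (m/z, intensity) vectors with
subject/replicate/group metadata and a processing-stage marker.  Sets of
spectra that share a common m/z grid are held in a :class:`SpectrumSet`,
the unit on which pointwise statistics and replicate averaging operate.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Group",
    "Stage",
    "Spectrum",
    "SpectrumSet",
    "SpectrumValidationError",
    "SpectrumParseError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectrum_mzml",
    "write_spectrum_mzml",
    "resample_to_common_grid",
    "average_replicates",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


class SpectrumValidationError(ValueError):
    """Raised when spectrum data violates a structural invariant."""


class Group(str, Enum):
    QC = "QC"
    CIN0 = "CIN0"
    CIN3 = "CIN3"
    OTHER = "other"


class Stage(str, Enum):
    RAW = "raw"
    BASELINE_CORRECTED = "baseline_corrected"
    NORMALIZED = "normalized"
    DENOISED = "denoised"
    SMOOTHED = "smoothed"


# Forward-only pipeline order.  Denoising (detection path) and smoothing
# (quantification path) both branch off the normalized stage.
_STAGE_ORDER = {
    Stage.RAW: 0,
    Stage.BASELINE_CORRECTED: 1,
    Stage.NORMALIZED: 2,
    Stage.DENOISED: 3,
    Stage.SMOOTHED: 3,
}


@dataclass
class Spectrum:
    """A single TOF mass spectrum on an increasing m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray
    id: str = ""
    subject: str = ""
    replicate: int = 0
    group: Group = Group.OTHER
    stage: Stage = Stage.RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if isinstance(self.group, str) and not isinstance(self.group, Group):
            self.group = Group(self.group)
        if isinstance(self.stage, str) and not isinstance(self.stage, Stage):
            self.stage = Stage(self.stage)
        self.validate()

    def validate(self) -> None:
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumValidationError("mz and intensity must be 1-D")
        if len(self.mz) != len(self.intensity):
            raise SpectrumValidationError(
                f"length mismatch: {len(self.mz)} mz vs {len(self.intensity)} intensities"
            )
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise SpectrumValidationError("non-finite values in spectrum")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise SpectrumValidationError("mz must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    def with_stage(self, stage: Stage, intensity: np.ndarray | None = None) -> "Spectrum":
        """Return a copy advanced to ``stage`` (stage transitions are forward-only)."""
        stage = Stage(stage)
        if _STAGE_ORDER[stage] < _STAGE_ORDER[self.stage]:
            raise SpectrumValidationError(
                f"cannot move stage backwards: {self.stage.value} -> {stage.value}"
            )
        new_int = self.intensity if intensity is None else np.asarray(intensity, float)
        return replace(self, intensity=new_int.copy(), mz=self.mz.copy(), stage=stage)


@dataclass
class SpectrumSet:
    """A collection of spectra, optionally sharing a common m/z grid."""

    spectra: list[Spectrum]
    common_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.common_grid is not None:
            self.common_grid = np.asarray(self.common_grid, dtype=float)
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise SpectrumValidationError("spectrum ids must be unique within a set")
        if self.common_grid is not None:
            for s in self.spectra:
                if len(s.mz) != len(self.common_grid) or not np.array_equal(
                    s.mz, self.common_grid
                ):
                    raise SpectrumValidationError(
                        f"spectrum {s.id!r} is not on the common grid"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    @property
    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) matrix; requires a common grid."""
        if self.common_grid is None:
            raise SpectrumValidationError("intensity_matrix requires a common grid")
        return np.vstack([s.intensity for s in self.spectra])


# ---------------------------------------------------------------------------
# CSV I/O


def read_spectrum_csv(path: str | Path, meta: dict | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) CSV into a raw-stage Spectrum.

    A single header line is auto-detected (first row with a non-numeric
    first field).  Rows are sorted by m/z; duplicate m/z values are a
    validation error.
    """
    path = Path(path)
    meta = dict(meta or {})
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header line
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            if not (np.isfinite(mz) and np.isfinite(inten)):
                raise SpectrumParseError(f"{path}:{lineno}: non-finite value")
            rows.append((mz, inten))
    if not rows:
        raise SpectrumParseError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise SpectrumValidationError(f"{path}: duplicate m/z values after sort")
    return Spectrum(
        mz=arr[:, 0],
        intensity=arr[:, 1],
        id=str(meta.pop("id", path.stem)),
        subject=str(meta.pop("subject", "")),
        replicate=int(meta.pop("replicate", 0)),
        group=Group(meta.pop("group", Group.OTHER)),
        stage=Stage.RAW,
        meta=meta,
    )


def write_spectrum_csv(s: Spectrum, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("mz,intensity\n")
        for m, y in zip(s.mz, s.intensity):
            fh.write(f"{float(m)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# Minimal mzML I/O (profile MS1 spectra, uncompressed 64-bit arrays).
#
# Only the subset needed for round-tripping spectrum sets is supported;
# no vendor library for mzML is assumed to be available at run time.

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{len(values)}d", *np.asarray(values, float))
    ).decode("ascii")


def _decode_array(text: str, n: int) -> np.ndarray:
    raw = base64.b64decode(text)
    return np.asarray(struct.unpack(f"<{len(raw) // 8}d", raw), dtype=float)[:n]


def write_spectrum_mzml(spectra: SpectrumSet | Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as minimal mzML (uncompressed little-endian 64-bit arrays)."""
    if isinstance(spectra, SpectrumSet):
        spectra = spectra.spectra
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0">',
        f'  <run id="run1">',
        f'    <spectrumList count="{len(spectra)}">',
    ]
    for i, s in enumerate(spectra):
        sid = s.id or f"scan={i}"
        attrs = (
            f'subject={s.subject};replicate={s.replicate};'
            f'group={s.group.value};stage={s.stage.value}'
        )
        lines += [
            f'      <spectrum index="{i}" id="{sid}" defaultArrayLength="{len(s)}">',
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
            f'        <userParam name="seldikit_meta" value="{attrs}"/>',
            '        <binaryDataArrayList count="2">',
        ]
        for accession, name, arr in (
            ("MS:1000514", "m/z array", s.mz),
            ("MS:1000515", "intensity array", s.intensity),
        ):
            b64 = _encode_array(arr)
            lines += [
                f'          <binaryDataArray encodedLength="{len(b64)}">',
                '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>',
                '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>',
                f'            <cvParam cvRef="MS" accession="{accession}" name="{name}"/>',
                f'            <binary>{b64}</binary>',
                "          </binaryDataArray>",
            ]
        lines += ["        </binaryDataArrayList>", "      </spectrum>"]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))


def read_spectrum_mzml(path: str | Path) -> SpectrumSet:
    """Read MS1 spectra from an mzML file into a SpectrumSet.

    Raises :class:`SpectrumParseError` on truncated/invalid XML or
    spectra with missing m/z or intensity arrays.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise SpectrumParseError(f"{path}: invalid mzML ({exc})") from exc
    ns = {"m": _MZML_NS}
    spectra: list[Spectrum] = []
    for sp in tree.getroot().iter(f"{{{_MZML_NS}}}spectrum"):
        n = int(sp.get("defaultArrayLength", "0"))
        sid = sp.get("id", f"scan={len(spectra)}")
        mz = inten = None
        for bda in sp.findall(".//m:binaryDataArray", ns):
            names = {cv.get("accession") for cv in bda.findall("m:cvParam", ns)}
            binary = bda.find("m:binary", ns)
            if binary is None or binary.text is None:
                raise SpectrumParseError(f"{path}: spectrum {sid!r} missing binary data")
            arr = _decode_array(binary.text, n)
            if "MS:1000514" in names:
                mz = arr
            elif "MS:1000515" in names:
                inten = arr
        if mz is None or inten is None:
            raise SpectrumParseError(
                f"{path}: spectrum {sid!r} lacks m/z or intensity array"
            )
        meta: dict[str, str] = {}
        for up in sp.findall("m:userParam", ns):
            if up.get("name") == "seldikit_meta":
                for kv in up.get("value", "").split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        meta[k] = v
        spectra.append(
            Spectrum(
                mz=mz,
                intensity=inten,
                id=sid,
                subject=meta.get("subject", ""),
                replicate=int(meta.get("replicate", 0)),
                group=Group(meta.get("group", "other")),
                stage=Stage(meta.get("stage", "raw")),
            )
        )
    return SpectrumSet(spectra=spectra)


# ---------------------------------------------------------------------------
# Grid harmonization and replicate averaging


def resample_to_common_grid(
    sset: SpectrumSet, grid: np.ndarray | None = None
) -> SpectrumSet:
    """Linearly interpolate every spectrum onto a shared m/z grid.

    Defaults to the grid of the first spectrum.  The grid must lie within
    the m/z span of every member spectrum.
    """
    if not sset.spectra:
        return SpectrumSet(spectra=[], common_grid=grid)
    if grid is None:
        grid = sset.spectra[0].mz
    grid = np.asarray(grid, dtype=float)
    out = []
    for s in sset:
        if grid[0] < s.mz[0] or grid[-1] > s.mz[-1]:
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] outside span of spectrum {s.id!r} "
                f"[{s.mz[0]}, {s.mz[-1]}]"
            )
        if len(s.mz) == len(grid) and np.array_equal(s.mz, grid):
            out.append(replace(s, mz=grid.copy(), intensity=s.intensity.copy()))
        else:
            out.append(
                replace(s, mz=grid.copy(), intensity=np.interp(grid, s.mz, s.intensity))
            )
    return SpectrumSet(spectra=out, common_grid=grid)


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Average replicate spectra per subject into one spectrum per subject.

    Spectra must share a common grid.  Mixed group labels within one
    subject are a validation error; subject order of first appearance is
    preserved.
    """
    if sset.common_grid is None:
        raise SpectrumValidationError("average_replicates requires a common grid")
    by_subject: dict[str, list[Spectrum]] = {}
    for s in sset:
        by_subject.setdefault(s.subject or s.id, []).append(s)
    out = []
    for subject, members in by_subject.items():
        groups = {m.group for m in members}
        if len(groups) > 1:
            raise SpectrumValidationError(
                f"subject {subject!r} has mixed group labels: {sorted(g.value for g in groups)}"
            )
        mean_int = np.mean([m.intensity for m in members], axis=0)
        proto = members[0]
        out.append(
            Spectrum(
                mz=sset.common_grid.copy(),
                intensity=mean_int,
                id=subject,
                subject=subject,
                replicate=0,
                group=proto.group,
                stage=proto.stage,
                meta={"n_replicates": len(members)},
            )
        )
    return SpectrumSet(spectra=out, common_grid=sset.common_grid.copy())
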