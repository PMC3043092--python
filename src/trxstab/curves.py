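"""Core containers: emission spectra and one-dimensional denaturation curves.

Both containers are thin, validated wrappers around numpy arrays with a
small amount of condition metadata, plus a plain-CSV serialisation
(``# key=json`` header comments carry the metadata) so that every
synthetic dataset round-trips through files bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AXIS_KINDS = ("denaturant", "temperature", "pH")
PROBES = ("fluorescence", "cd", "ans", "sec", "dsc")


@dataclass
class EmissionSpectrum:
    """A fluorescence emission spectrum at one solution condition.

    Parameters
    ----------
    wavelengths : array of float
        Emission wavelengths in nm, strictly increasing.
    intensities : array of float
        Fluorescence intensities (arbitrary units), non-negative,
        same length as ``wavelengths``.
    axis_kind : str
        Which condition axis this spectrum belongs to
        (``denaturant`` | ``temperature`` | ``pH``).
    condition : float
        Value of that condition (M, degC or pH units).
    excitation_nm : float, optional
        Excitation wavelength in nm.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    axis_kind: str
    condition: float
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("need at least two wavelength points")
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("negative fluorescence intensity")

    def to_csv(self, path: str | Path) -> None:
        meta = {
            "axis_kind": self.axis_kind,
            "condition": self.condition,
            "excitation_nm": self.excitation_nm,
        }
        with open(path, "w") as fh:
            for key, val in meta.items():
                fh.write(f"# {key}={json.dumps(val)}\n")
            fh.write("wavelength_nm,intensity\n")
            for wl, ii in zip(self.wavelengths, self.intensities):
                fh.write(f"{float(wl)!r},{float(ii)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionSpectrum":
        meta, frame = _read_commented_csv(path)
        return cls(
            wavelengths=frame["wavelength_nm"].to_numpy(),
            intensities=frame["intensity"].to_numpy(),
            axis_kind=meta.get("axis_kind", "pH"),
            condition=meta.get("condition", 0.0),
            excitation_nm=meta.get("excitation_nm"),
        )


@dataclass
class DenaturationCurve:
    """Ordered (condition, signal) observations for one spectroscopic probe.

    Observations are sorted by ``x`` on construction. Exact duplicate
    points are collapsed; duplicated ``x`` with conflicting ``y`` raises,
    so that fits stay reproducible rather than silently averaging.
    """

    axis_kind: str
    x: np.ndarray
    y: np.ndarray
    probe: str = "fluorescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        keep = np.ones(x.size, dtype=bool)
        for i in range(1, x.size):
            if x[i] == x[i - 1]:
                if y[i] != y[i - 1]:
                    raise ValueError(
                        f"duplicate x={x[i]} with conflicting y values"
                    )
                keep[i] = False
        self.x, self.y = x[keep], y[keep]

    def __len__(self) -> int:
        return self.x.size

    @property
    def amplitude(self) -> float:
        return float(np.ptp(self.y))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# axis_kind={json.dumps(self.axis_kind)}\n")
            fh.write(f"# probe={json.dumps(self.probe)}\n")
            for key, val in self.meta.items():
                fh.write(f"# {key}={json.dumps(val)}\n")
            fh.write("x,y\n")
            for xx, yy in zip(self.x, self.y):
                fh.write(f"{float(xx)!r},{float(yy)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DenaturationCurve":
        meta, frame = _read_commented_csv(path)
        axis_kind = meta.pop("axis_kind", "denaturant")
        probe = meta.pop("probe", "fluorescence")
        return cls(
            axis_kind=axis_kind,
            x=frame["x"].to_numpy(),
            y=frame["y"].to_numpy(),
            probe=probe,
            meta=meta,
        )


def _read_commented_csv(path: str | Path) -> tuple[dict, pd.DataFrame]:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, raw = line[1:].strip().partition("=")
            meta[key.strip()] = json.loads(raw)
        else:
            body_start = i
            break
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines[body_start:])), float_precision="round_trip")
    return meta, frame
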