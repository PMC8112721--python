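"""Bundled benchmark data and plain-text sample readers.

Two classical carbon-fibre lifetime benchmarks ship with the package:

* ``carbon_fibers_tensile`` — tensile strength (GPa) of 69 single carbon
  fibres;
* ``carbon_fibers_breaking`` — breaking stress of 66 carbon fibres.

Both are widely used complete samples for benchmarking extended-Weibull
lifetime models.  The file reader accepts one value per line,
comma/whitespace-separated text, and single-column CSV with an optional
header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dataset",
    "FIXTURES",
    "load_dataset",
    "write_dataset",
]

CARBON_FIBERS_TENSILE = (
    0.312, 0.314, 0.479, 0.552, 0.700, 0.803, 0.861, 0.865, 0.944, 0.958,
    0.966, 0.997, 1.006, 1.021, 1.027, 1.055, 1.063, 1.098, 1.140, 1.179,
    1.224, 1.240, 1.253, 1.270, 1.272, 1.274, 1.301, 1.301, 1.359, 1.382,
    1.382, 1.426, 1.434, 1.435, 1.478, 1.490, 1.511, 1.514, 1.535, 1.554,
    1.566, 1.570, 1.586, 1.629, 1.633, 1.642, 1.648, 1.684, 1.697, 1.726,
    1.770, 1.773, 1.800, 1.809, 1.818, 1.821, 1.848, 1.880, 1.954, 2.012,
    2.067, 2.084, 2.090, 2.096, 2.128, 2.233, 2.433, 2.585, 2.585,
)

CARBON_FIBERS_BREAKING = (
    3.70, 2.74, 2.73, 2.50, 3.60, 3.11, 3.27, 2.87, 1.47, 3.11,
    3.56, 4.42, 2.41, 3.19, 3.22, 1.69, 3.28, 3.09, 1.87, 3.15,
    4.90, 1.57, 2.67, 2.93, 3.22, 3.39, 2.81, 4.20, 3.33, 2.55,
    3.31, 3.31, 2.85, 1.25, 4.38, 1.84, 0.39, 3.68, 2.48, 0.85,
    1.61, 2.79, 4.70, 2.03, 1.89, 2.88, 2.82, 2.05, 3.65, 3.75,
    2.43, 2.95, 2.97, 3.39, 2.96, 2.35, 2.55, 2.59, 2.03, 1.61,
    2.12, 3.15, 1.08, 2.56, 1.80, 2.53,
)

FIXTURES: dict[str, tuple[float, ...]] = {
    "carbon_fibers_tensile": CARBON_FIBERS_TENSILE,
    "carbon_fibers_breaking": CARBON_FIBERS_BREAKING,
}


@dataclass(frozen=True)
class Dataset:
    """A labelled univariate sample: values, name and source kind."""

    values: np.ndarray
    name: str
    source: str  # "fixture" or "file"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("dataset contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


def _parse_file(path: str) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.replace(",", " ").split()
            for tok in tokens:
                try:
                    values.append(float(tok))
                except ValueError:
                    # tolerate a single header line in CSV-style input
                    if lineno == 1:
                        values = []
                        break
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric token {tok!r}"
                    ) from None
    if not values:
        raise ValueError(f"{path}: no numeric data found")
    return np.asarray(values, dtype=float)


def load_dataset(path_or_name: str) -> Dataset:
    """Load a bundled fixture by name, or a sample from a plain-text file."""
    if path_or_name in FIXTURES:
        return Dataset(
            values=np.asarray(FIXTURES[path_or_name], dtype=float),
            name=path_or_name,
            source="fixture",
        )
    if not os.path.exists(path_or_name):
        raise FileNotFoundError(
            f"{path_or_name!r} is neither a file nor a fixture name "
            f"(fixtures: {sorted(FIXTURES)})"
        )
    return Dataset(
        values=_parse_file(path_or_name),
        name=os.path.basename(path_or_name),
        source="file",
    )


def write_dataset(path: str, values) -> None:
    """Write a sample one value per line (full repr precision round-trips)."""
    v = np.asarray(values, dtype=float).ravel()
    with open(path, "w") as fh:
        for x in v:
            fh.write(f"{float(x)!r}\n")
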