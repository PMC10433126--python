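"""Minimal NRRD reader/writer for cubic scalar grids (ASCII encoding).

Covers exactly what the toolkit needs: 3-D double or uint8 fields with
isotropic spacing, written with ``encoding: ascii`` so the files are plain
text and readable by any conforming NRRD implementation.
"""

from __future__ import annotations

import numpy as np

from .dose import GridSpec
from .errors import ValidationError

__all__ = ["write_nrrd", "read_nrrd"]

_MAGIC = "NRRD0004"
_TYPES = {"double": np.float64, "uint8": np.uint8}


def write_nrrd(path, values: np.ndarray, spec: GridSpec) -> None:
    values = np.asarray(values)
    if values.shape != spec.shape:
        raise ValidationError(f"array shape {values.shape} != grid {spec.shape}")
    if values.dtype == np.uint8 or values.dtype == bool:
        typ, arr, fmt = "uint8", values.astype(np.uint8), "%d"
    else:
        typ, arr, fmt = "double", values.astype(np.float64), "%.17g"
    n, s = spec.n_per_axis, spec.spacing
    header = (
        f"{_MAGIC}\n"
        f"type: {typ}\n"
        "dimension: 3\n"
        f"sizes: {n} {n} {n}\n"
        f"spacings: {s:.17g} {s:.17g} {s:.17g}\n"
        "encoding: ascii\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        flat = arr.ravel(order="C")
        for i in range(0, flat.size, 8):
            fh.write(" ".join(fmt % v for v in flat[i : i + 8]) + "\n")


def read_nrrd(path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        magic = fh.readline().strip()
        if not magic.startswith("NRRD"):
            raise ValidationError(f"{path}: not an NRRD file")
        fields = {}
        for line in fh:
            line = line.strip()
            if not line:
                break
            if line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            fields[key.strip().lower()] = val.strip()
        if fields.get("encoding") != "ascii":
            raise ValidationError(f"{path}: only ascii encoding is supported")
        if fields.get("dimension") != "3":
            raise ValidationError(f"{path}: only 3-D grids are supported")
        typ = fields.get("type", "double")
        if typ not in _TYPES:
            raise ValidationError(f"{path}: unsupported type {typ!r}")
        sizes = [int(x) for x in fields["sizes"].split()]
        spacings = [float(x) for x in fields["spacings"].split()]
        if len(set(sizes)) != 1 or len(set(spacings)) != 1:
            raise ValidationError(f"{path}: only cubic isotropic grids supported")
        data = np.loadtxt(fh, dtype=_TYPES[typ]).ravel()
    if data.size != int(np.prod(sizes)):
        raise ValidationError(f"{path}: data length does not match sizes")
    spec = GridSpec(n_per_axis=sizes[0], spacing=spacings[0])
    return data.reshape(sizes, order="C"), spec
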