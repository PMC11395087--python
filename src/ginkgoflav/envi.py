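"""Minimal ENVI-style hypercube I/O.

Cubes are stored as an ASCII ``.hdr`` header plus a raw binary raster in
band-interleaved-by-line (BIL) order, 32-bit little-endian floats.  Only the
small subset of the ENVI header dialect that this pipeline emits is parsed:
``samples``, ``lines``, ``bands``, ``data type``, ``interleave``,
``byte order`` and the ``wavelength`` list.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

_DTYPE = np.dtype("<f4")  # ENVI data type 4, byte order 0


def write_envi(path_base: str | Path, cube: np.ndarray, wavelengths) -> Path:
    """Write ``cube`` (lines x samples x bands) to ``path_base{.img,.hdr}``.

    Returns the path of the binary raster.
    """
    cube = np.asarray(cube, dtype=float)
    if cube.ndim == 2:  # single-band frame
        cube = cube[:, :, None]
    if cube.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D array, got shape {cube.shape}")
    lines, samples, bands = cube.shape
    wavelengths = np.asarray(wavelengths, dtype=float).ravel()
    if wavelengths.size != bands:
        raise ValueError(
            f"wavelength list length {wavelengths.size} != band count {bands}"
        )
    base = Path(path_base)
    img_path = base.with_suffix(".img")
    hdr_path = base.with_suffix(".hdr")
    wl = ", ".join(f"{w:.4f}" for w in wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    # BIL layout: line-major, then band, then sample.
    bil = np.ascontiguousarray(cube.transpose(0, 2, 1), dtype=_DTYPE)
    bil.tofile(img_path)
    return img_path


def _parse_header(hdr_text: str) -> dict:
    fields: dict = {}
    # brace-delimited lists may span lines
    for m in re.finditer(r"(?ms)^([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)$", hdr_text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
    return fields


def read_envi(path_base: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ENVI cube written by :func:`write_envi`.

    Returns ``(cube, wavelengths)`` with cube shaped lines x samples x bands.
    """
    base = Path(path_base)
    hdr_path = base if base.suffix == ".hdr" else base.with_suffix(".hdr")
    img_path = hdr_path.with_suffix(".img")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header: {hdr_path}")
    if not img_path.exists():
        raise FileNotFoundError(f"missing ENVI raster: {img_path}")
    fields = _parse_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} lacks field {exc}") from exc
    if fields.get("data type", "4") != "4":
        raise ValueError("only data type 4 (float32) is supported")
    if fields.get("interleave", "bil").lower() != "bil":
        raise ValueError("only BIL interleave is supported")
    wl_field = fields.get("wavelength", "{}").strip("{} \n")
    wavelengths = np.array(
        [float(tok) for tok in wl_field.split(",") if tok.strip()], dtype=float
    )
    data = np.fromfile(img_path, dtype=_DTYPE)
    expected = lines * samples * bands
    if data.size != expected:
        raise ValueError(
            f"raster {img_path} holds {data.size} values, expected {expected}"
        )
    cube = data.reshape(lines, bands, samples).transpose(0, 2, 1).astype(float)
    if wavelengths.size == 0:
        wavelengths = np.arange(bands, dtype=float)
    return cube, wavelengths
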