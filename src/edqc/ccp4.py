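"""Optional CCP4/MRC map adapter (boundary format support only).

Reads and writes mode-2 (float32) maps with orthogonal 90° cells and axis
order X, Y, Z.  Anything else — skewed cells, permuted axes, symmetry — is
rejected; the computational core works on :class:`~edqc.density.DensityGrid`
and this adapter only converts at the boundary.
"""

from __future__ import annotations

import struct

import numpy as np

from .density import DensityGrid

__all__ = ["read_ccp4", "write_ccp4"]

_HEADER_WORDS = 256
_MAP_MAGIC = b"MAP "


def read_ccp4(data: bytes) -> DensityGrid:
    if len(data) < _HEADER_WORDS * 4:
        raise ValueError("truncated CCP4 header")
    ints = struct.unpack("<10i", data[0:40])
    nc, nr, ns, mode = ints[0], ints[1], ints[2], ints[3]
    start = ints[4:7]
    mxyz = ints[7:10]
    cell = struct.unpack("<6f", data[40:64])
    mapc, mapr, maps_ = struct.unpack("<3i", data[64:76])
    nsymbt = struct.unpack("<i", data[92:96])[0]
    if data[208:212] != _MAP_MAGIC:
        raise ValueError("missing MAP magic word")
    if mode != 2:
        raise ValueError(f"unsupported CCP4 mode {mode} (only mode 2 float32)")
    if (mapc, mapr, maps_) != (1, 2, 3):
        raise ValueError("unsupported axis order (only X, Y, Z)")
    if not all(abs(a - 90.0) < 1e-3 for a in cell[3:]):
        raise ValueError("non-orthogonal cell")
    spacing = [cell[i] / mxyz[i] for i in range(3)]
    offset = _HEADER_WORDS * 4 + nsymbt
    count = nc * nr * ns
    vals = np.frombuffer(data, dtype="<f4", count=count, offset=offset).astype(float)
    # CCP4 stores column-fastest (x fastest); DensityGrid is row-major (z fastest)
    vals = vals.reshape(ns, nr, nc).transpose(2, 1, 0)
    origin = [start[i] * spacing[i] for i in range(3)]
    return DensityGrid(origin=origin, spacing=spacing, dims=(nc, nr, ns), values=vals)


def write_ccp4(grid: DensityGrid) -> bytes:
    nx, ny, nz = grid.dims
    start = grid.origin / grid.spacing
    if not np.allclose(start, np.round(start), atol=1e-4):
        raise ValueError("origin must be an integer number of voxels for CCP4 output")
    start = np.round(start).astype(int)
    cell = [grid.spacing[i] * grid.dims[i] for i in range(3)]
    vals = grid.values.astype("<f4")
    header = bytearray(_HEADER_WORDS * 4)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, *start, nx, ny, nz)
    struct.pack_into("<6f", header, 40, *cell, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into(
        "<3f", header, 76, float(vals.min()), float(vals.max()), float(vals.mean())
    )
    struct.pack_into("<2i", header, 88, 1, 0)  # ISPG=P1, NSYMBT=0
    header[208:212] = _MAP_MAGIC
    header[212:216] = b"DA\x00\x00"  # little-endian machine stamp
    body = vals.transpose(2, 1, 0).tobytes()
    return bytes(header) + body
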