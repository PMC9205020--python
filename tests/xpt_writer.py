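"""Minimal numeric-only SAS transport (XPT v5) writer.

Synthetic test-fixture builder: produces just enough of the transport format
(library/member/namestr/obs records, IBM hexadecimal floating point) for
``pandas.read_sas(format="xport")`` to parse a small numeric table.  Not part
of the package surface; used only to craft XPT fixtures at test time.
"""

from __future__ import annotations

import struct

import numpy as np
import pandas as pd

_REC = 80


def _pad(s: str, n: int) -> bytes:
    return s.ljust(n)[:n].encode("ascii")


def _ibm_double(x: float) -> bytes:
    """IEEE double -> 8-byte big-endian IBM hexadecimal float."""
    if x == 0 or not np.isfinite(x):
        return b"\x00" * 8
    sign = 0x80 if x < 0 else 0x00
    m, e = np.frexp(abs(x))          # abs(x) = m * 2**e, m in [0.5, 1)
    E = int(np.ceil(e / 4.0))        # abs(x) = f * 16**E, f in [1/16, 1)
    f = m * 2.0 ** (e - 4 * E)
    frac = int(round(f * 2**56))
    if frac >= 2**56:                # rounding overflow into the next digit
        frac >>= 4
        E += 1
    b0 = sign | (E + 64)
    return bytes([b0]) + frac.to_bytes(7, "big")


def write_xpt(df: pd.DataFrame, path: str, dsname: str = "DATA") -> None:
    """Write a numeric DataFrame as a single-member XPT v5 file."""
    cols = list(df.columns)
    if any(not np.issubdtype(df[c].dtype, np.number) for c in cols):
        raise ValueError("numeric columns only")
    ts = "01JAN20:00:00:00"
    out = bytearray()
    out += _pad("HEADER RECORD*******LIBRARY HEADER RECORD!!!!!!!"
                "000000000000000000000000000000", _REC)
    out += _pad(f"{'SAS':<8}{'SAS':<8}{'SASLIB':<8}{'9.4':<8}{'X64_SRV':<8}"
                + " " * 24 + ts, _REC)
    out += _pad(ts, _REC)
    out += _pad("HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
                "000000000000000001600000000140", _REC)
    out += _pad("HEADER RECORD*******DSCRPTR HEADER RECORD!!!!!!!"
                "000000000000000000000000000000", _REC)
    out += _pad(f"{'SAS':<8}{dsname:<8}{'SASDATA':<8}{'9.4':<8}{'X64_SRV':<8}"
                + " " * 24 + ts, _REC)
    out += _pad(ts + " " * 16 + " " * 40 + " " * 8, _REC)
    out += _pad("HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!"
                f"000000{len(cols):04d}00000000000000000000", _REC)
    for i, name in enumerate(cols):
        ns = struct.pack(
            ">hhhh8s40s8shhh2s8shhl52s",
            1, 0, 8, i + 1,
            _pad(str(name).upper(), 8), _pad(str(name), 40), _pad("BEST", 8),
            0, 0, 0, b"  ", _pad("", 8), 0, 0, i * 8, b" " * 52,
        )
        assert len(ns) == 140
        out += ns
    if len(out) % _REC:
        out += b" " * (_REC - len(out) % _REC)
    out += _pad("HEADER RECORD*******OBS     HEADER RECORD!!!!!!!"
                "000000000000000000000000000000", _REC)
    for _, row in df.iterrows():
        for c in cols:
            out += _ibm_double(float(row[c]))
    if len(out) % _REC:
        out += b" " * (_REC - len(out) % _REC)
    with open(path, "wb") as fh:
        fh.write(bytes(out))
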