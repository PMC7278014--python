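"""Minimal EDF writer for test fixtures (synthetic data only).

Writes a spec-compliant single-record EDF file: 256-byte global header,
256 bytes of per-signal header fields, then little-endian int16 samples.
Quantisation to int16 over the physical range loses precision, so tests
compare shapes/labels/rates, not exact sample values.
"""

import numpy as np


def _f(value, width):
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data, fs, labels):
    """Write channels x samples microvolt data as one EDF data record."""
    data = np.asarray(data, dtype=float)
    ns, n = data.shape
    assert len(labels) == ns
    duration = n / fs
    pmin, pmax = -1000.0, 1000.0
    dmin, dmax = -32768, 32767

    header = b"".join([
        _f("0", 8),
        _f("X X X X", 80),
        _f("Startdate X X X X", 80),
        _f("01.01.20", 8),
        _f("00.00.00", 8),
        _f(256 * (ns + 1), 8),
        _f("", 44),
        _f(1, 8),
        _f(f"{duration:g}", 8),
        _f(ns, 4),
    ])
    header += b"".join(_f(lab, 16) for lab in labels)
    header += b"".join(_f("AgAgCl electrode", 80) for _ in labels)
    header += b"".join(_f("uV", 8) for _ in labels)
    header += b"".join(_f(f"{pmin:g}", 8) for _ in labels)
    header += b"".join(_f(f"{pmax:g}", 8) for _ in labels)
    header += b"".join(_f(dmin, 8) for _ in labels)
    header += b"".join(_f(dmax, 8) for _ in labels)
    header += b"".join(_f("", 80) for _ in labels)
    header += b"".join(_f(n, 8) for _ in labels)
    header += b"".join(_f("", 32) for _ in labels)
    assert len(header) == 256 * (ns + 1)

    scaled = np.clip((data - pmin) / (pmax - pmin), 0, 1)
    digital = (scaled * (dmax - dmin) + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
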