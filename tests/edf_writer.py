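"""Minimal EDF writer for test fixtures (synthetic data only).

Writes a spec-compliant single-record EDF file: 256-byte global header,
256 bytes of per-signal header fields, little-endian int16 samples.  Only
what the reader contract needs — no annotations, one data record.
"""

import numpy as np


def _field(text, width):
    b = str(text).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, data, fs, labels=None):
    """Write channels x samples float data as one EDF data record."""
    data = np.asarray(data, dtype=float)
    ns, m = data.shape
    if labels is None:
        labels = [f"ch{i}" for i in range(ns)]
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip((data - phys_min) * scale + dig_min, dig_min, dig_max)
    digital = digital.astype("<i2")

    record_duration = m / fs
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.20", 8),
            _field("00.00.00", 8),
            _field(256 * (1 + ns), 8),
            _field("", 44),
            _field(1, 8),  # one data record
            _field(f"{record_duration:g}", 8),
            _field(ns, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field("uV", 8) for _ in range(ns)),
            b"".join(_field(f"{phys_min:g}", 8) for _ in range(ns)),
            b"".join(_field(f"{phys_max:g}", 8) for _ in range(ns)),
            b"".join(_field(dig_min, 8) for _ in range(ns)),
            b"".join(_field(dig_max, 8) for _ in range(ns)),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(m, 8) for _ in range(ns)),
            b"".join(_field("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as f:
        f.write(header)
        f.write(per_signal)
        f.write(digital.tobytes())
    return path
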