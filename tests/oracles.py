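"""Independent brute-force oracles used only by the test suite.

These are deliberately naive transcriptions of the definitions, kept
separate from the package implementations they validate.
"""

from __future__ import annotations

import struct

import numpy as np


def lz76_count_brute(s: str) -> int:
    """LZ76 exhaustive-history word count, straight from the definition.

    Scan left to right; the current word closes one symbol after its
    longest prefix that can be reproduced from the preceding history
    (an occurrence may start anywhere before the word and extend into
    it, i.e. substring of history + word-minus-last-symbol).
    """
    n = len(s)
    p = 0
    count = 0
    while p < n:
        length = 0
        while p + length < n and s[p : p + length + 1] in s[: p + length]:
            length += 1
        count += 1
        p += length + 1
    return count


def bh_adjust_brute(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values from the definition.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        candidate = m * p[order[rank - 1]] / rank
        running_min = min(running_min, candidate)
        adj_sorted[rank - 1] = min(running_min, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def write_minimal_edf(path, data_uv: np.ndarray, rate_hz: float, labels) -> None:
    """Write a one-record EDF file (16-bit), for exercising the EDF reader.

    Synthetic stand-in for a device export: a minimal but conformant
    header and a single data record holding the whole signal.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    n_ch, n_samp = data_uv.shape
    phys_min, phys_max = -3276.8, 3276.7
    dig_min, dig_max = -32768, 32767
    record_duration = n_samp / rate_hz

    def fld(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            fld("0", 8),
            fld("X X X X", 80),
            fld("Startdate X X X X", 80),
            fld("01.01.20", 8),
            fld("00.00.00", 8),
            fld(256 * (n_ch + 1), 8),
            fld("", 44),
            fld(1, 8),
            fld(f"{record_duration:g}", 8),
            fld(n_ch, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(fld(lab, 16) for lab in labels),
            b"".join(fld("", 80) for _ in labels),
            b"".join(fld("uV", 8) for _ in labels),
            b"".join(fld(phys_min, 8) for _ in labels),
            b"".join(fld(phys_max, 8) for _ in labels),
            b"".join(fld(dig_min, 8) for _ in labels),
            b"".join(fld(dig_max, 8) for _ in labels),
            b"".join(fld("", 80) for _ in labels),
            b"".join(fld(n_samp, 8) for _ in labels),
            b"".join(fld("", 32) for _ in labels),
        ]
    )
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data_uv - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for ch in range(n_ch):
            fh.write(struct.pack(f"<{n_samp}h", *digital[ch]))
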