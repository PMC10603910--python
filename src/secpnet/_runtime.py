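"""Process-level performance knobs for training-sized workloads.

Two host behaviours otherwise dominate the runtime of the numpy tape:

* a multi-threaded BLAS spends more on pool coordination than on the small
  matrix products used here (and on a single-core host the spinning workers
  are catastrophic), so the thread pool is pinned to one thread;
* glibc serves the tape's many large, short-lived buffers with mmap and
  returns them to the kernel on free, so every training step pays page-fault
  costs on first touch; raising the malloc mmap/trim thresholds keeps the
  buffers on the heap where they are recycled.

:func:`configure_runtime` applies both, is idempotent, and is called by the
CLI, the test suite and the staged-training entry point.  Library users who
prefer their own threading/allocator policy can simply not call it.
"""

from __future__ import annotations

import ctypes
import os

__all__ = ["configure_runtime", "limit_blas_threads", "tune_malloc"]

_ENV_VARS = (
    "OPENBLAS_NUM_THREADS",
    "OMP_NUM_THREADS",
    "MKL_NUM_THREADS",
    "BLIS_NUM_THREADS",
)

_M_TRIM_THRESHOLD = -1
_M_MMAP_THRESHOLD = -3

_configured = False


def limit_blas_threads(n: int = 1) -> None:
    """Best-effort cap on BLAS threads, effective even after numpy import."""
    for var in _ENV_VARS:
        os.environ.setdefault(var, str(n))
    for name in (
        "libopenblas.so.0",
        "libopenblas.so",
        "libopenblasp-r0.so.0",
        "libscipy_openblas.so",
    ):
        try:
            lib = ctypes.CDLL(name)
            lib.openblas_set_num_threads(int(n))
            return
        except (OSError, AttributeError):
            continue


def tune_malloc(mmap_threshold: int = 1 << 30) -> None:
    """Keep large freed buffers on the glibc heap for reuse."""
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(_M_MMAP_THRESHOLD, int(mmap_threshold))
        libc.mallopt(_M_TRIM_THRESHOLD, 2**31 - 1)
    except (OSError, AttributeError):  # pragma: no cover - non-glibc hosts
        pass


def configure_runtime() -> None:
    global _configured
    if _configured:
        return
    limit_blas_threads(1)
    tune_malloc()
    _configured = True
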