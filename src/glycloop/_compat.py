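"""Optional numba acceleration.

Numerical cores are written as plain-numpy functions that compile cleanly
under ``numba.njit`` when numba is importable; otherwise the interpreted
versions run unchanged (slower but identical results).
"""

from __future__ import annotations

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


__all__ = ["njit", "HAVE_NUMBA"]
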