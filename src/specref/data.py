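"""Reflectivity datasets and fitting-space transforms.

The on-disk dialect is the plain-text 3/4-column format common to
reflectometry reducers: columns are Q (Å⁻¹), R, dR with dR one standard
deviation of R, and optionally dQ, the FWHM of the Gaussian instrument
resolution function at that point.  ``#``-prefixed comments and non-numeric
header lines are skipped; whitespace or comma delimiters are accepted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

__all__ = ["Data1D", "Transform"]


class Data1D:
    """One measured reflectivity curve.

    Attributes
    ----------
    q : ndarray — momentum transfer, Å⁻¹ (strictly positive, ascending)
    r : ndarray — reflectivity
    dr : ndarray — 1-σ uncertainty of r (> 0)
    dq : ndarray or None — per-point resolution FWHM, Å⁻¹ (>= 0)
    name : str
    """

    def __init__(self, q, r, dr, dq=None, name=""):
        q = np.asarray(q, dtype=float).ravel()
        r = np.asarray(r, dtype=float).ravel()
        dr = np.asarray(dr, dtype=float).ravel()
        if not (q.size == r.size == dr.size):
            raise ValueError("q, r, dr must have equal lengths")
        if dq is not None:
            dq = np.asarray(dq, dtype=float).ravel()
            if dq.size != q.size:
                raise ValueError("dq length mismatch")
            if np.any(dq < 0):
                raise ValueError("dq must be >= 0")
        if np.any(q <= 0):
            raise ValueError("Q must be strictly positive")
        if np.any(dr <= 0):
            raise ValueError("dR must be > 0")
        order = np.argsort(q, kind="stable")
        self.q = q[order]
        self.r = r[order]
        self.dr = dr[order]
        self.dq = dq[order] if dq is not None else None
        self.name = name

    def __len__(self):
        return self.q.size

    def __repr__(self):
        cols = 4 if self.dq is not None else 3
        return f"<Data1D {self.name!r}, {len(self)} points, {cols} columns>"

    # -- I/O -------------------------------------------------------------
    @classmethod
    def load(cls, path):
        """Read a 3- or 4-column plain-text reflectivity file."""
        path = Path(path)
        rows = []
        ncols = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.replace(",", " ").split()
                try:
                    vals = [float(p) for p in parts]
                except ValueError:
                    # non-numeric header line
                    continue
                if len(vals) < 3:
                    raise ValueError(
                        f"{path.name}:{lineno}: expected >= 3 numeric columns, got {len(vals)}"
                    )
                if ncols is None:
                    ncols = min(len(vals), 4)
                    if len(vals) > 4:
                        warnings.warn(
                            f"{path.name}: {len(vals)} columns found, using the first 4",
                            stacklevel=2,
                        )
                elif len(vals) < ncols:
                    raise ValueError(
                        f"{path.name}:{lineno}: ragged row ({len(vals)} columns, expected {ncols})"
                    )
                rows.append(vals[:ncols])
        if not rows:
            raise ValueError(f"{path.name}: no numeric data rows found")
        arr = np.array(rows, dtype=float)
        dq = arr[:, 3] if ncols == 4 else None
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], dq=dq, name=path.stem)

    def save(self, path):
        """Write in the same 3/4-column plain-text dialect."""
        path = Path(path)
        cols = [self.q, self.r, self.dr]
        if self.dq is not None:
            cols.append(self.dq)
        header = "Q (1/A) R dR" + (" dQ_FWHM (1/A)" if self.dq is not None else "")
        np.savetxt(path, np.column_stack(cols), fmt="%.15e", header=header)
        return path


class Transform:
    """Fitting-space transform of (R, dR) pairs.

    kind ``'none'`` fits R vs Q, ``'logY'`` fits log₁₀R vs Q, ``'YX4'``
    fits R·Q⁴ vs Q.  Uncertainties follow first-order propagation.
    """

    KINDS = ("none", "logY", "YX4")

    def __init__(self, kind="none"):
        if kind is None:
            kind = "none"
        if kind not in self.KINDS:
            raise ValueError(f"unknown transform {kind!r}; choose from {self.KINDS}")
        self.kind = kind

    def __call__(self, q, r, dr=None):
        """Return (y, dy) in fitting space; dy is None when dr is None."""
        q = np.asarray(q, dtype=float)
        r = np.asarray(r, dtype=float)
        if self.kind == "none":
            return (r, None if dr is None else np.asarray(dr, dtype=float))
        if self.kind == "logY":
            bad = np.flatnonzero(r <= 0)
            if bad.size:
                raise ValueError(f"logY transform requires R > 0; offending indices {bad.tolist()}")
            y = np.log10(r)
            dy = None if dr is None else np.asarray(dr, dtype=float) / (r * np.log(10.0))
            return (y, dy)
        # YX4
        y = r * q**4
        dy = None if dr is None else np.asarray(dr, dtype=float) * q**4
        return (y, dy)

    def __repr__(self):
        return f"Transform({self.kind!r})"
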