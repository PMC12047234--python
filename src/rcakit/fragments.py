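"""Fragmentomics: length profiles and fixed-signature NMF tumor fraction.

cfDNA fragment lengths are summarized as a normalized 1-bp histogram on
30-220 bp and decomposed against two fixed nonnegative length signatures:
Signature 1 (healthy-dominant, mono-nucleosomal mode near 167 bp) and
Signature 2 (tumor-indicative, shifted shorter with a 10-bp periodicity).
The contribution of Signature 2, normalized by the total contribution,
is the fragmentomics tumor-fraction estimate, capped at 1.0.

The packaged default signatures are parametric stand-ins built from the
synthetic fragment-length model; externally derived signatures can be
supplied as a two-column TSV and used instead (see ``rcakit.io``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import nnls

from .synth import FragmentLengthModel

__all__ = [
    "LengthProfile",
    "SignatureMatrix",
    "build_length_profile",
    "nmf_tf",
    "default_signatures",
    "afm_nm_to_bp",
]

NMF_LO, NMF_HI = 30, 220


@dataclass(frozen=True)
class LengthProfile:
    """Normalized 1-bp fragment-length histogram on [lo, hi]."""

    lo: int
    hi: int
    density: np.ndarray

    def __post_init__(self) -> None:
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", dens)
        if len(dens) != self.hi - self.lo + 1:
            raise ValueError("density length must equal hi - lo + 1")
        if np.any(dens < 0):
            raise ValueError("densities must be nonnegative")
        if not np.isclose(dens.sum(), 1.0, atol=1e-8):
            raise ValueError("profile must be normalized to sum 1")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    @property
    def mode(self) -> int:
        return int(self.lengths[int(np.argmax(self.density))])


@dataclass(frozen=True)
class SignatureMatrix:
    """Two fixed nonnegative length signatures on a shared support.

    Row 1 is the healthy-dominant signature, row 2 the tumor-indicative
    one; each row sums to 1.  ``label`` records provenance (packaged
    parametric stand-in vs. user-supplied TSV).
    """

    lo: int
    hi: int
    sig1: np.ndarray
    sig2: np.ndarray
    label: str = "parametric-standin"

    def __post_init__(self) -> None:
        s1 = np.asarray(self.sig1, dtype=float)
        s2 = np.asarray(self.sig2, dtype=float)
        object.__setattr__(self, "sig1", s1)
        object.__setattr__(self, "sig2", s2)
        n = self.hi - self.lo + 1
        if len(s1) != n or len(s2) != n:
            raise ValueError("signature length must equal hi - lo + 1")
        if np.any(s1 < 0) or np.any(s2 < 0):
            raise ValueError("signatures must be nonnegative")
        for s in (s1, s2):
            if not np.isclose(s.sum(), 1.0, atol=1e-8):
                raise ValueError("each signature must sum to 1")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)


def build_length_profile(lengths, lo: int = NMF_LO, hi: int = NMF_HI) -> LengthProfile:
    """1-bp histogram of ``lengths`` on [lo, hi], normalized to sum 1.

    Out-of-range lengths are dropped; an error is raised if nothing
    remains in range.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("lengths must be nonempty")
    in_range = arr[(arr >= lo) & (arr <= hi)]
    if in_range.size == 0:
        raise ValueError(f"no fragment lengths inside [{lo}, {hi}]")
    counts = np.bincount(in_range - lo, minlength=hi - lo + 1).astype(float)
    return LengthProfile(lo=lo, hi=hi, density=counts / counts.sum())


def nmf_tf(profile: LengthProfile, signatures: SignatureMatrix) -> float:
    """Fragmentomics tumor fraction from a fixed-signature decomposition.

    Solves min ||w1*S1 + w2*S2 - profile||_2 subject to w >= 0 (the
    single-step equivalent of NMF with a frozen basis) and returns
    w2 / (w1 + w2), capped at 1.0.
    """
    if (profile.lo, profile.hi) != (signatures.lo, signatures.hi):
        raise ValueError(
            f"support mismatch: profile [{profile.lo}, {profile.hi}] vs "
            f"signatures [{signatures.lo}, {signatures.hi}]"
        )
    if not np.any(profile.density > 0):
        raise ValueError("profile is all zero")
    A = np.column_stack([signatures.sig1, signatures.sig2])
    w, _ = nnls(A, profile.density)
    total = w.sum()
    if total == 0:
        raise ValueError("degenerate decomposition: both signature weights are zero")
    return min(float(w[1] / total), 1.0)


def default_signatures(
    model: FragmentLengthModel | None = None,
    periodicity_amp: float = 0.5,
    lo: int = NMF_LO,
    hi: int = NMF_HI,
) -> SignatureMatrix:
    """Packaged parametric stand-in signatures.

    Signature 1 is the healthy fragment-length density restricted to
    [lo, hi]; Signature 2 is the tumor-shifted density with a 10-bp
    periodicity of amplitude ``periodicity_amp``.  Both are renormalized
    on the restricted support.
    """
    model = model or FragmentLengthModel()
    tumor_model = replace(model, periodicity_amp=periodicity_amp)
    support = model.support
    sel = (support >= lo) & (support <= hi)
    s1 = model.healthy_pmf()[sel]
    s2 = tumor_model.tumor_pmf()[sel]
    return SignatureMatrix(
        lo=lo, hi=hi, sig1=s1 / s1.sum(), sig2=s2 / s2.sum(), label="parametric-standin"
    )


def afm_nm_to_bp(length_nm: float) -> float:
    """Convert an AFM fiber length in nm to bp: L_bp = (L_nm + 10) / 0.341.

    The offset and slope come from calibrating traced fiber lengths
    against a DNA ladder of known fragment sizes.
    """
    if length_nm < 0:
        raise ValueError("length_nm must be nonnegative")
    return (length_nm + 10.0) / 0.341
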