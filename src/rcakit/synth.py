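"""Seeded synthetic-data generators for the whole pipeline.

Everything downstream — consensus calling, error-rate measurement,
SNV-based and fragmentomics-based tumor-fraction estimation, and the
limit-of-detection simulator — can be exercised on data produced here.
The generators emulate the statistical structure of cell-free DNA
sequencing experiments:

* bimodal fragment lengths with mono- and di-nucleosomal modes near
  167 bp and 332 bp, with tumor-derived fragments shifted ~4-5 bp
  shorter and optionally carrying a 10-bp periodicity;
* tumor-informed variant panels (site, REF, ALT, biopsy VAF, purity);
* concatemer reads: repeated copies of one template fragment with iid
  substitution errors, as produced by rolling-circle amplification;
* per-read allele observations (REF / MUT / ERR) at panel sites with
  sequencing timestamps;
* in-silico admixtures of two observation sets.

All generators accept either an integer seed or a ``numpy`` Generator
and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AlignedRead, phred_from_rate

__all__ = [
    "BASES",
    "CALL_REF",
    "CALL_MUT",
    "CALL_ERR",
    "CALLS",
    "RUN_MINUTES",
    "FragmentLengthModel",
    "VariantSite",
    "VariantPanel",
    "Template",
    "ConcatemerRead",
    "AlleleObservations",
    "default_repeat_dist",
    "generate_fragment_lengths",
    "generate_variant_panel",
    "generate_templates",
    "generate_concatemer_reads",
    "generate_allele_observations",
    "make_admixture",
    "generate_reference",
    "generate_aligned_reads",
]

BASES = "ACGT"
CALL_REF, CALL_MUT, CALL_ERR = "REF", "MUT", "ERR"
CALLS = (CALL_REF, CALL_MUT, CALL_ERR)

#: Default sequencing run duration (72 h) used for read timestamps, minutes.
RUN_MINUTES = 72 * 60.0

#: Periodicity modulation only applies below this length (sub-mononucleosomal
#: fragments are where the 10-bp ladder is visible in tumor cfDNA).
_PERIODICITY_MAX_BP = 170


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Fragment lengths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentLengthModel:
    """Discrete cfDNA fragment-length distribution.

    The healthy distribution is a two-component truncated normal mixture
    with modes at ``mono_mode`` and ``di_mode``.  The tumor variant of the
    same model shifts both modes down by ``tumor_shift`` base pairs and,
    when ``periodicity_amp > 0``, multiplies the sub-170 bp density by a
    10-bp cosine modulation phased on the shifted mono-nucleosomal mode.

    Parameters (all lengths in bp):

    mono_mode, di_mode
        Mono- and di-nucleosomal modes (defaults 167 and 332).
    mono_sd, di_sd
        Spread of the two components (defaults 12 and 10; the narrower
        di-nucleosomal component keeps the secondary mode resolvable in
        a 100,000-fragment histogram).
    di_weight
        Mixture weight of the di-nucleosomal component (default 0.15).
    tumor_shift
        Shortening of tumor-derived fragments (default 4.5).
    periodicity_amp
        Amplitude in [0, 1] of the 10-bp modulation applied to the tumor
        variant; 0 disables it (healthy profiles are never modulated).
    min_len, max_len
        Support bounds of the discrete distribution (defaults 30, 700).
    """

    mono_mode: float = 167.0
    di_mode: float = 332.0
    mono_sd: float = 12.0
    di_sd: float = 10.0
    di_weight: float = 0.15
    tumor_shift: float = 4.5
    periodicity_amp: float = 0.0
    min_len: int = 30
    max_len: int = 700

    def __post_init__(self) -> None:
        if not (self.min_len < self.max_len):
            raise ValueError("min_len must be < max_len")
        if not (self.min_len <= self.mono_mode <= self.max_len):
            raise ValueError("mono_mode outside [min_len, max_len]")
        if not (self.min_len <= self.di_mode <= self.max_len):
            raise ValueError("di_mode outside [min_len, max_len]")
        if not 0.0 <= self.di_weight <= 1.0:
            raise ValueError("di_weight must be in [0, 1]")
        if not 0.0 <= self.periodicity_amp <= 1.0:
            raise ValueError("periodicity_amp must be in [0, 1]")
        if self.mono_sd <= 0 or self.di_sd <= 0:
            raise ValueError("component sds must be positive")
        if self.tumor_shift < 0:
            raise ValueError("tumor_shift must be nonnegative")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.min_len, self.max_len + 1)

    def _mixture_density(self, mono_mode: float, di_mode: float) -> np.ndarray:
        x = self.support.astype(float)
        dens = (1.0 - self.di_weight) * stats.norm.pdf(x, mono_mode, self.mono_sd)
        dens = dens + self.di_weight * stats.norm.pdf(x, di_mode, self.di_sd)
        return dens / dens.sum()

    def healthy_pmf(self) -> np.ndarray:
        """Probability of each length in ``support`` for healthy cfDNA."""
        return self._mixture_density(self.mono_mode, self.di_mode)

    def tumor_pmf(self) -> np.ndarray:
        """Probability of each length in ``support`` for tumor cfDNA."""
        mono = self.mono_mode - self.tumor_shift
        dens = self._mixture_density(mono, self.di_mode - self.tumor_shift)
        if self.periodicity_amp > 0:
            x = self.support.astype(float)
            mod = 1.0 + self.periodicity_amp * np.cos(2 * np.pi * (x - mono) / 10.0)
            short = x < _PERIODICITY_MAX_BP
            dens = np.where(short, dens * mod, dens)
            dens = dens / dens.sum()
        return dens


def generate_fragment_lengths(
    n: int,
    model: FragmentLengthModel | None = None,
    tumor_fraction: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` integer fragment lengths from a healthy/tumor mixture.

    Each fragment is tumor-derived with probability ``tumor_fraction`` and
    healthy otherwise; draws come from the corresponding discrete pmf of
    ``model``.  Returned lengths are integers in [min_len, max_len].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    model = model or FragmentLengthModel()
    rng = as_rng(seed)
    n_tumor = int(rng.binomial(n, tumor_fraction))
    out = np.empty(n, dtype=np.int64)
    support = model.support
    if n_tumor:
        out[:n_tumor] = rng.choice(support, size=n_tumor, p=model.tumor_pmf())
    if n - n_tumor:
        out[n_tumor:] = rng.choice(support, size=n - n_tumor, p=model.healthy_pmf())
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# Variant panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSite:
    """One tumor-informed somatic SNV. ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt bases must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("sites must be single-nucleotide variants")
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"vaf must be in (0, 1], got {self.vaf}")


@dataclass(frozen=True)
class VariantPanel:
    """A tumor-informed SNV panel plus the biopsy's tumor purity."""

    sites: tuple[VariantSite, ...]
    purity: float

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("panel must contain at least one site")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        keys = {(s.chrom, s.pos) for s in self.sites}
        if len(keys) != len(self.sites):
            raise ValueError("panel positions must be unique per chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def vafs(self) -> np.ndarray:
        return np.array([s.vaf for s in self.sites])

    def mut_probabilities(self) -> np.ndarray:
        """Per-site probability purity*VAF that a tumor fragment is MUT."""
        return self.purity * self.vafs


def generate_variant_panel(
    n_sites: int,
    vaf_mean: float = 0.3,
    vaf_sd: float = 0.15,
    purity: float = 1.0,
    seed: int | np.random.Generator | None = None,
    chroms: Sequence[str] = tuple(str(c) for c in range(1, 23)),
    chrom_span: int = 100_000_000,
) -> VariantPanel:
    """Generate a synthetic tumor-informed SNV panel.

    VAFs are drawn from a normal distribution truncated to (0, 1]
    (degenerate at ``vaf_mean`` when ``vaf_sd == 0``); positions are
    globally unique and assigned round-robin over ``chroms``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if vaf_sd < 0:
        raise ValueError("vaf_sd must be nonnegative")
    rng = as_rng(seed)
    if vaf_sd == 0:
        vafs = np.full(n_sites, float(vaf_mean))
    else:
        lo, hi = 1e-6, 1.0
        a, b = (lo - vaf_mean) / vaf_sd, (hi - vaf_mean) / vaf_sd
        vafs = stats.truncnorm.rvs(a, b, loc=vaf_mean, scale=vaf_sd, size=n_sites, random_state=rng)
    if np.any((vafs <= 0) | (vafs > 1)):
        raise ValueError("generated VAFs outside (0, 1]")
    positions = rng.choice(chrom_span, size=n_sites, replace=False)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = []
    for i in range(n_sites):
        sites.append(
            VariantSite(
                chrom=chroms[i % len(chroms)],
                pos=int(positions[i]),
                ref=BASES[ref_idx[i]],
                alt=BASES[alt_idx[i]],
                vaf=float(vafs[i]),
            )
        )
    sites.sort(key=lambda s: (chroms.index(s.chrom) if s.chrom in chroms else s.chrom, s.pos))
    return VariantPanel(sites=tuple(sites), purity=float(purity))


# ---------------------------------------------------------------------------
# Concatemer reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Template:
    """An original cfDNA fragment before circularization and RCA."""

    template_id: str
    seq: str
    chrom: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class ConcatemerRead:
    """Repeated, error-bearing copies (subreads) of one template.

    The substitution-only error model keeps every subread the same length
    as the template, so subreads are column-aligned by construction.
    """

    template_id: str
    template_seq: str
    template_coords: tuple[str, int, int]
    subreads: tuple[str, ...]
    subread_quals: tuple[tuple[int, ...], ...]
    backbone_len: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if not self.template_seq:
            raise ValueError("template sequence must be nonempty")
        if len(self.subreads) < 1:
            raise ValueError("a concatemer carries at least one subread")
        L = len(self.template_seq)
        for s in self.subreads:
            if len(s) != L:
                raise ValueError("subreads must have the template's length (substitution-only model)")
        if len(self.subread_quals) != len(self.subreads):
            raise ValueError("one quality vector per subread required")
        for q in self.subread_quals:
            if len(q) != L:
                raise ValueError("quality vectors must have the template's length")

    @property
    def n_repeats(self) -> int:
        return len(self.subreads)


def default_repeat_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    """Repeat counts per concatemer: 1 + Poisson(5), median 6, minimum 1."""
    return 1 + rng.poisson(5.0, size=size)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def generate_templates(
    n: int,
    model: FragmentLengthModel | None = None,
    tumor_fraction: float = 0.0,
    seed: int | np.random.Generator | None = None,
    chrom: str = "1",
    chrom_span: int = 100_000_000,
) -> list[Template]:
    """Random template fragments with lengths from the fragment model."""
    rng = as_rng(seed)
    lengths = generate_fragment_lengths(n, model, tumor_fraction, rng)
    starts = rng.integers(0, chrom_span, size=n)
    return [
        Template(
            template_id=f"tmpl{i:06d}",
            seq=_random_seq(rng, int(lengths[i])),
            chrom=chrom,
            start=int(starts[i]),
        )
        for i in range(n)
    ]


def _mutate(seq_codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply iid substitutions; a wrong base is uniform over the 3 others."""
    out = seq_codes.copy()
    hit = rng.random(out.shape) < error_rate
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def generate_concatemer_reads(
    templates: Sequence[Template],
    repeat_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    error_rate: float = 0.00674,
    seed: int | np.random.Generator | None = None,
    backbone_len: int = 40,
    run_minutes: float = RUN_MINUTES,
) -> list[ConcatemerRead]:
    """One concatemer per template: repeat count from ``repeat_dist`` and
    iid per-base substitutions at ``error_rate`` in every subread.

    Subread base qualities are set to the Phred value of ``error_rate``
    (capped at 60), the quality a calibrated basecaller would emit.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    for t in templates:
        if not t.seq:
            raise ValueError("template sequence must be nonempty")
    rng = as_rng(seed)
    repeat_dist = repeat_dist or default_repeat_dist
    repeats = np.asarray(repeat_dist(rng, len(templates)), dtype=np.int64)
    if np.any(repeats < 1):
        raise ValueError("repeat_dist produced a count < 1")
    qual = phred_from_rate(error_rate, zero_cap=60)
    timestamps = rng.uniform(0.0, run_minutes, size=len(templates))

    code = {b: i for i, b in enumerate(BASES)}
    reads: list[ConcatemerRead] = []
    for i, t in enumerate(templates):
        codes = np.array([code[b] for b in t.seq], dtype=np.int64)
        r = int(repeats[i])
        sub_codes = _mutate(np.tile(codes, (r, 1)), error_rate, rng)
        subreads = tuple("".join(BASES[c] for c in row) for row in sub_codes)
        quals = tuple(tuple([qual] * len(t.seq)) for _ in range(r))
        reads.append(
            ConcatemerRead(
                template_id=t.template_id,
                template_seq=t.seq,
                template_coords=t.coords,
                subreads=subreads,
                subread_quals=quals,
                backbone_len=backbone_len,
                timestamp=float(timestamps[i]),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Allele observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleObservations:
    """Per-read allele calls at tumor-informed panel sites.

    ``call`` entries are "REF", "MUT" or "ERR"; ``timestamp`` is minutes
    since run start.  ``n_sites`` records the size of the panel the
    observations were drawn against so that sets can be checked for
    compatibility before mixing.
    """

    site_index: np.ndarray
    call: np.ndarray
    timestamp: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_index", np.asarray(self.site_index, dtype=np.int64))
        object.__setattr__(self, "call", np.asarray(self.call, dtype="U3"))
        object.__setattr__(self, "timestamp", np.asarray(self.timestamp, dtype=float))
        if not (len(self.site_index) == len(self.call) == len(self.timestamp)):
            raise ValueError("site_index, call and timestamp must have equal length")
        if len(self.site_index) and (
            self.site_index.min() < 0 or self.site_index.max() >= self.n_sites
        ):
            raise ValueError("site_index out of range for the panel")
        bad = set(np.unique(self.call)) - set(CALLS)
        if bad:
            raise ValueError(f"unknown call symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.site_index)


def generate_allele_observations(
    panel: VariantPanel,
    tf: float,
    coverage: float,
    error_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    run_minutes: float = RUN_MINUTES,
) -> AlleleObservations:
    """Simulate per-read allele calls at every panel site.

    Per site the read count is Poisson(``coverage``).  Each read is
    tumor-derived with probability ``tf``; a tumor read is MUT with
    probability purity*VAF (else REF).  A healthy read is never truly
    mutant, but a sequencing error (probability ``error_rate``) turns it
    into the site's ALT allele one time in three (recorded MUT) and into
    one of the two other alleles otherwise (recorded ERR).
    """
    if tf < 0 or tf > 1:
        raise ValueError("tf must be in [0, 1]")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = as_rng(seed)
    per_site = rng.poisson(coverage, size=panel.n_sites)
    site_index = np.repeat(np.arange(panel.n_sites), per_site)
    n = len(site_index)
    calls = np.full(n, CALL_REF, dtype="U3")
    if n:
        p_mut = panel.mut_probabilities()[site_index]
        tumor = rng.random(n) < tf
        calls[tumor & (rng.random(n) < p_mut)] = CALL_MUT
        u = rng.random(n)
        healthy = ~tumor
        calls[healthy & (u < error_rate / 3.0)] = CALL_MUT
        calls[healthy & (u >= error_rate / 3.0) & (u < error_rate)] = CALL_ERR
    ts = np.sort(rng.uniform(0.0, run_minutes, size=n))
    order = rng.permutation(n)
    return AlleleObservations(
        site_index=site_index[order], call=calls[order], timestamp=ts, n_sites=panel.n_sites
    )


def make_admixture(
    obs_tumor: AlleleObservations,
    obs_healthy: AlleleObservations,
    fraction: float,
    seed: int | np.random.Generator | None = None,
) -> AlleleObservations:
    """Thin two observation sets into an in-silico admixture.

    Each tumor record is kept with probability ``fraction`` and each
    healthy record with probability ``1 - fraction``, so the output size
    matches the inputs in expectation and the MUT content scales with
    ``fraction``.  Both sets must come from the same panel.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if obs_tumor.n_sites != obs_healthy.n_sites:
        raise ValueError("observation sets were drawn against different panels")
    rng = as_rng(seed)
    keep_t = rng.random(len(obs_tumor)) < fraction
    keep_h = rng.random(len(obs_healthy)) < (1.0 - fraction)
    site = np.concatenate([obs_tumor.site_index[keep_t], obs_healthy.site_index[keep_h]])
    call = np.concatenate([obs_tumor.call[keep_t], obs_healthy.call[keep_h]])
    ts = np.concatenate([obs_tumor.timestamp[keep_t], obs_healthy.timestamp[keep_h]])
    order = np.argsort(ts, kind="stable")
    return AlleleObservations(
        site_index=site[order], call=call[order], timestamp=ts[order], n_sites=obs_tumor.n_sites
    )


# ---------------------------------------------------------------------------
# Aligned reads for error-rate measurement
# ---------------------------------------------------------------------------


def generate_reference(
    chrom_lengths: Mapping[str, int], seed: int | np.random.Generator | None = None
) -> dict[str, str]:
    """Random reference sequences, one per chromosome."""
    rng = as_rng(seed)
    return {c: _random_seq(rng, n) for c, n in chrom_lengths.items()}


def generate_aligned_reads(
    reference: Mapping[str, str],
    n_reads: int,
    read_len: int,
    error_rate: float,
    mapq: int = 60,
    seed: int | np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Reads copied from the reference with iid substitutions at ``error_rate``."""
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = as_rng(seed)
    chroms = list(reference)
    weights = np.array([max(len(reference[c]) - read_len + 1, 0) for c in chroms], dtype=float)
    if weights.sum() == 0:
        raise ValueError("reference too short for the requested read length")
    weights /= weights.sum()
    code = {b: i for i, b in enumerate(BASES)}
    reads: list[AlignedRead] = []
    picks = rng.choice(len(chroms), size=n_reads, p=weights)
    for k in range(n_reads):
        chrom = chroms[picks[k]]
        start = int(rng.integers(0, len(reference[chrom]) - read_len + 1))
        codes = np.array([code[b] for b in reference[chrom][start : start + read_len]])
        mutated = _mutate(codes, error_rate, rng)
        reads.append(
            AlignedRead(
                chrom=chrom,
                start=start,
                seq="".join(BASES[c] for c in mutated),
                mapq=mapq,
            )
        )
    return reads
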