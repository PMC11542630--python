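"""Synonymous-substitution (Ks) estimation, density peaks, and dating.

The pairwise estimator is Nei–Gojobori (1986): fractional synonymous site
counts per codon, averaging of synonymous/nonsynonymous differences over all
shortest mutational pathways between differing codons, and the Jukes–Cantor
multiple-hit correction ds = −(3/4)·ln(1 − (4/3)·ps).  Pathways passing
through stop codons are excluded from the average (steps to or from a stop
count as nonsynonymous in the rare case no stop-free pathway exists), and
mutations to stop codons count as nonsynonymous in site counting.

Ohnolog divergence times follow the molecular clock T = Ks / (2r), with the
Cyprinidae synonymous rate r = 3.51 × 10⁻⁹ substitutions per synonymous site
per year as default.  Peaks of the Ks distribution are located on a Gaussian
kernel density estimate; because low Ks values sit on a substitution-count
lattice (Ks = Sd/S with small integer Sd), the bandwidth can be floored at a
multiple of the lattice spacing 1/S when dating (see ``lattice_bandwidth``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import signal, stats
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "KsRecord",
    "KsDensity",
    "TimeEstimate",
    "pairwise_ks",
    "ks_density",
    "lattice_bandwidth",
    "ks_to_time",
    "wilcoxon_signed_rank",
    "ortholog_asymmetry_test",
    "AsymmetryRecord",
    "AsymmetryReport",
    "DEFAULT_RATE",
    "SENSE_CODONS",
    "STOP_CODONS",
]

DEFAULT_RATE = 3.51e-9  # substitutions / synonymous site / year (Cyprinidae)

_BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))
_AA = dict(standard_dna_table.forward_table)


class KsError(ValueError):
    """Invalid input to the Ks estimator."""


# ---------------------------------------------------------------------------
# NG86 tables


@lru_cache(maxsize=1)
def _site_table() -> dict[str, tuple[float, float]]:
    """Per sense codon: (synonymous sites, nonsynonymous sites).

    Each of the three positions contributes the fraction of its three
    alternative bases whose substitution is synonymous; changes creating a
    stop codon count as nonsynonymous.
    """
    table: dict[str, tuple[float, float]] = {}
    for codon in SENSE_CODONS:
        syn = 0.0
        for pos in range(3):
            for base in _BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if alt not in STOP_CODONS and _AA[alt] == _AA[codon]:
                    syn += 1 / 3
        table[codon] = (syn, 3.0 - syn)
    return table


@lru_cache(maxsize=8192)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    All orderings of the differing positions are considered; pathways through
    a stop codon are dropped.  If every pathway is blocked, all pathways are
    used with stop-involving steps counted as nonsynonymous.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return (0.0, 0.0)

    def walk(order, allow_stops):
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and _AA[cur] == _AA[nxt]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return (sd, nd)

    results = [r for o in itertools.permutations(diffs) if (r := walk(o, False))]
    if not results:
        results = [walk(o, True) for o in itertools.permutations(diffs)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return (sd, nd)


# ---------------------------------------------------------------------------
# Pairwise Ks


@dataclass
class KsRecord:
    """NG86 bookkeeping for one sequence pair."""

    pair: tuple[str, str]
    family: str | None
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    ps: float
    ks: float  # JC-corrected; NaN when invalid
    valid: bool
    n_codons: int
    n_skipped: int

    def __post_init__(self):
        if self.valid and self.ks < 0:
            raise KsError("negative Ks on a valid record")


def _codon_ok(codon: str) -> bool:
    return codon in _AA  # sense codon, unambiguous, no gaps


def pairwise_ks(
    cds_a: str,
    cds_b: str,
    pair: tuple[str, str] = ("a", "b"),
    family: str | None = None,
) -> KsRecord:
    """NG86 pairwise Ks between two in-frame coding sequences.

    Sequences must have equal length divisible by 3.  Codons containing
    gaps, ambiguity codes or stop codons in either sequence are skipped (and
    counted in ``n_skipped``).  When the synonymous difference proportion
    ps ≥ 3/4 the Jukes–Cantor correction is undefined and the record is
    flagged invalid.
    """
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise KsError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise KsError(f"sequence length {len(a)} not a multiple of 3")
    sites = _site_table()
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if not (_codon_ok(ca) and _codon_ok(cb)):
            skipped += 1
            continue
        sa, na = sites[ca]
        sb, nb = sites[cb]
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
        used += 1
    if used == 0:
        raise KsError("no usable codons in alignment")
    ps = Sd / S if S > 0 else 0.0
    if ps >= 0.75:
        return KsRecord(pair, family, S, N, Sd, Nd, ps, float("nan"), False, used, skipped)
    ks = -0.75 * math.log1p(-4.0 * ps / 3.0)
    return KsRecord(pair, family, S, N, Sd, Nd, ps, ks, True, used, skipped)


# ---------------------------------------------------------------------------
# Density and peaks


@dataclass
class KsDensity:
    """Gaussian-kernel density of Ks values with located peak(s)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peak: float
    peak_density: float
    local_peaks: list[float] = field(default_factory=list)
    n: int = 0

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _silverman(values: np.ndarray) -> float:
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0.0:
        return 0.0
    return 0.9 * spread * len(values) ** (-0.2)


def lattice_bandwidth(site_counts: Iterable[float], mult: float = 1.5) -> float:
    """Bandwidth floor from the Ks count lattice: ``mult``/median(S).

    With few synonymous differences per family, Ks values concentrate on
    multiples of 1/S; a kernel narrower than that spacing resolves the
    lattice and the argmax degenerates to the most populated count.  Flooring
    the bandwidth at 1.5 lattice units restores a smooth unimodal density.
    """
    s = np.asarray(list(site_counts), dtype=float)
    if s.size == 0 or np.median(s) <= 0:
        return 0.0
    return mult / float(np.median(s))


def ks_density(
    values: Sequence[float],
    bandwidth: float | str = "auto",
    grid_size: int = 2048,
    min_values: int = 10,
    prominence_frac: float = 0.05,
    min_bandwidth: float = 0.0,
) -> KsDensity:
    """Gaussian KDE of Ks values on [0, 1.1·max]; peak = grid argmax.

    ``bandwidth="auto"`` applies Silverman's rule (optionally floored at
    ``min_bandwidth``); an explicit float is used verbatim.  Local peaks with
    prominence ≥ ``prominence_frac`` of the maximum density are reported in
    addition to the global peak.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size < min_values:
        raise ValueError(f"need at least {min_values} finite Ks values, got {vals.size}")
    if bandwidth == "auto":
        bw = max(_silverman(vals), min_bandwidth)
    else:
        bw = float(bandwidth)
    if bw <= 0:
        # All values identical (or explicit zero): degenerate point mass.
        bw = max(float(vals.max()) * 1e-3, 1e-6)
    hi = float(vals.max()) * 1.1 if vals.max() > 0 else 1.0
    grid = np.linspace(0.0, hi, grid_size)
    # Direct KDE evaluation; reflection at 0 preserves mass for peaks near 0.
    z = (grid[:, None] - vals[None, :]) / bw
    zr = (grid[:, None] + vals[None, :]) / bw
    dens = (np.exp(-0.5 * z**2) + np.exp(-0.5 * zr**2)).sum(axis=1)
    dens /= vals.size * bw * math.sqrt(2 * math.pi)
    imax = int(np.argmax(dens))
    idx, _ = signal.find_peaks(dens, prominence=prominence_frac * dens.max())
    local = [float(grid[i]) for i in idx]
    return KsDensity(
        grid=grid,
        density=dens,
        bandwidth=bw,
        peak=float(grid[imax]),
        peak_density=float(dens[imax]),
        local_peaks=local,
        n=int(vals.size),
    )


# ---------------------------------------------------------------------------
# Dating


@dataclass(frozen=True)
class TimeEstimate:
    """Molecular-clock divergence time T = Ks / (2r), reported in Mya."""

    T: float  # Mya
    ks: float
    r: float

    @property
    def T_rounded(self) -> float:
        return round(self.T, 2)

    def __str__(self) -> str:
        return f"{self.T:.2f} Mya (Ks={self.ks:.4g}, r={self.r:.3g})"


def ks_to_time(ks: float, r: float = DEFAULT_RATE) -> TimeEstimate:
    """Convert a Ks value to a divergence time in Mya via T = Ks/(2r)."""
    if r <= 0:
        raise ValueError(f"rate r must be positive, got {r}")
    if ks < 0:
        raise ValueError(f"Ks must be non-negative, got {ks}")
    return TimeEstimate(T=ks / (2.0 * r) / 1e6, ks=ks, r=r)


# ---------------------------------------------------------------------------
# Paired tests


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's convention); if all differences
    are zero the degenerate (W=0, p=1) is returned with a warning.  The exact
    null distribution is used for n ≤ 25 after zero removal when there are no
    ties; otherwise the normal approximation with continuity and tie
    correction applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return (0.0, 1.0)
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return (float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class AsymmetryRecord:
    """Per-family Ks of the two ohnologs against the diploid ortholog."""

    family: str
    ks_copy1: float
    ks_copy2: float
    subgenome1: str | None = None
    subgenome2: str | None = None


@dataclass
class AsymmetryReport:
    grouping: str
    statistic: float
    pvalue: float
    median_group1: float
    median_group2: float
    n_used: int
    n_skipped: int


def ortholog_asymmetry_test(
    records: Iterable[AsymmetryRecord],
    grouping: str = "larger-smaller",
    min_n: int = 6,
) -> AsymmetryReport:
    """Paired test for rate asymmetry between ohnolog copies.

    Each family contributes the Ks of its two ohnologs to the same diploid
    ortholog.  Under ``"larger-smaller"`` the larger value of each pair goes
    to group L and the smaller to group S — the deliberately liberal grouping
    used when copies cannot be assigned to subgenomes; under ``"subgenome"``
    the split follows the records' subgenome labels, the grouping under which
    true allopolyploids show consistent asymmetry.  Families with a missing
    (non-finite) value are skipped and counted.
    """
    if grouping not in {"larger-smaller", "subgenome"}:
        raise ValueError(f"unknown grouping {grouping!r}")
    g1: list[float] = []
    g2: list[float] = []
    skipped = 0
    for rec in records:
        if not (np.isfinite(rec.ks_copy1) and np.isfinite(rec.ks_copy2)):
            skipped += 1
            continue
        if grouping == "larger-smaller":
            g1.append(max(rec.ks_copy1, rec.ks_copy2))
            g2.append(min(rec.ks_copy1, rec.ks_copy2))
        else:
            if rec.subgenome1 is None or rec.subgenome2 is None:
                skipped += 1
                continue
            pairs = sorted(
                [(rec.subgenome1, rec.ks_copy1), (rec.subgenome2, rec.ks_copy2)]
            )
            g1.append(pairs[0][1])
            g2.append(pairs[1][1])
    if len(g1) < min_n:
        raise ValueError(f"need at least {min_n} usable families, got {len(g1)}")
    w, p = wilcoxon_signed_rank(g1, g2)
    return AsymmetryReport(
        grouping=grouping,
        statistic=w,
        pvalue=p,
        median_group1=float(np.median(g1)),
        median_group2=float(np.median(g2)),
        n_used=len(g1),
        n_skipped=skipped,
    )
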