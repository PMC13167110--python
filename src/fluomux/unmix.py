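"""Linear spectral unmixing and dual-pass fluorophore identity assignment.

Each ROI fingerprint is modelled as a nonnegative combination of reference
fluorophore fingerprints; the fitted multipliers (betas) are computed twice,
from the raw spectrum (``beta_raw``) and from the max-normalized spectrum
against max-normalized references (``beta_norm``) - the two channels have
complementary biases for bright and dim ROIs.  Identities are assigned per
subject: the baseline is the mean/SD of each fluorophore's betas over all ROIs
of that subject, a hit requires exceeding mean + k*SD (k = 1.5) in either
channel, and the fluorophore with the largest z-scored beta wins the primary
identity.  ROIs left unassigned are re-evaluated in a second pass with
thresholds proportionally lowered for over-represented fluorophores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectral import Fingerprint, ReferenceLibrary

__all__ = [
    "BetaVector",
    "BaselineStats",
    "AssignmentResult",
    "ShareProfile",
    "fit_betas",
    "fit_betas_many",
    "compute_baseline",
    "single_pass_assign",
    "dual_pass_assign",
    "classify_subject",
    "SpectralUnmixer",
    "UnmixResults",
]


@dataclass
class BetaVector:
    """Per-fluorophore unmixing multipliers for one ROI (raw and normalized)."""

    roi_id: str
    beta_raw: np.ndarray
    beta_norm: np.ndarray
    residual: float
    fluorophores: tuple[str, ...]

    def __post_init__(self):
        self.beta_raw = np.asarray(self.beta_raw, dtype=float)
        self.beta_norm = np.asarray(self.beta_norm, dtype=float)
        n = len(self.fluorophores)
        if self.beta_raw.shape != (n,) or self.beta_norm.shape != (n,):
            raise ValueError("beta lengths must equal library size")


def _solve(design: np.ndarray, target: np.ndarray, nonnegative: bool) -> np.ndarray:
    if nonnegative:
        beta, _ = nnls(design, target)
        return beta
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return beta


def fit_betas(
    spectrum: Fingerprint,
    library: ReferenceLibrary,
    nonnegative: bool = True,
) -> BetaVector:
    """Fit per-fluorophore beta multipliers to one ROI fingerprint.

    ``beta_raw`` minimizes ||spectrum - sum_f beta_f ref_f||^2 subject to
    beta >= 0 (nonnegative least squares; contributions are physically
    nonnegative).  ``beta_norm`` repeats the fit on the max-one-normalized
    spectrum against max-one-normalized references.  The reported residual is
    the raw-fit residual norm.
    """
    expected = (library.grid.n_lasers, library.grid.n_bins)
    if spectrum.shape != expected:
        raise ValueError(
            f"spectrum shape {spectrum.shape} does not match library grid {expected}"
        )
    names = tuple(library.names)
    y = spectrum.flatten()
    if not y.any():
        return BetaVector(spectrum.label, np.zeros(len(names)), np.zeros(len(names)), 0.0, names)
    design_raw = library.matrix()
    beta_raw = _solve(design_raw, y, nonnegative)
    residual = float(np.linalg.norm(y - design_raw @ beta_raw))
    design_norm = design_raw / design_raw.max(axis=0, keepdims=True)
    beta_norm = _solve(design_norm, y / y.max(), nonnegative)
    return BetaVector(spectrum.label, beta_raw, beta_norm, residual, names)


def fit_betas_many(
    spectra: list[Fingerprint],
    library: ReferenceLibrary,
    nonnegative: bool = True,
) -> list[BetaVector]:
    """Vector of :func:`fit_betas` over many ROIs, sharing one design matrix."""
    names = tuple(library.names)
    design_raw = library.matrix()
    design_norm = design_raw / design_raw.max(axis=0, keepdims=True)
    out = []
    zeros = np.zeros(len(names))
    for s in spectra:
        y = s.flatten()
        if not y.any():
            out.append(BetaVector(s.label, zeros.copy(), zeros.copy(), 0.0, names))
            continue
        beta_raw = _solve(design_raw, y, nonnegative)
        residual = float(np.linalg.norm(y - design_raw @ beta_raw))
        beta_norm = _solve(design_norm, y / y.max(), nonnegative)
        out.append(BetaVector(s.label, beta_raw, beta_norm, residual, names))
    return out


@dataclass
class BaselineStats:
    """Per-subject spectral baseline: mean/SD of betas over all ROIs.

    Cutoffs are mean + k*SD per fluorophore, computed independently for the
    raw and normalized channels with the population SD (deterministic at any
    ROI count).
    """

    fluorophores: tuple[str, ...]
    mean_raw: np.ndarray
    sd_raw: np.ndarray
    mean_norm: np.ndarray
    sd_norm: np.ndarray
    k: float = 1.5

    @property
    def cutoff_raw(self) -> np.ndarray:
        return self.mean_raw + self.k * self.sd_raw

    @property
    def cutoff_norm(self) -> np.ndarray:
        return self.mean_norm + self.k * self.sd_norm

    def zscores(self, beta: BetaVector) -> tuple[np.ndarray, np.ndarray]:
        """(z_raw, z_norm); zero where the baseline SD vanishes."""
        with np.errstate(invalid="ignore", divide="ignore"):
            z_raw = np.where(
                self.sd_raw > 0, (beta.beta_raw - self.mean_raw) / self.sd_raw, 0.0
            )
            z_norm = np.where(
                self.sd_norm > 0, (beta.beta_norm - self.mean_norm) / self.sd_norm, 0.0
            )
        return z_raw, z_norm


def compute_baseline(betas: list[BetaVector], k: float = 1.5) -> BaselineStats:
    """Mean, population SD and mean + k*SD cutoffs over a subject's ROIs."""
    if len(betas) < 2:
        raise ValueError("baseline requires at least two ROIs (SD undefined)")
    names = betas[0].fluorophores
    if any(b.fluorophores != names for b in betas):
        raise ValueError("beta vectors disagree on fluorophore order")
    raw = np.stack([b.beta_raw for b in betas])
    norm = np.stack([b.beta_norm for b in betas])
    return BaselineStats(
        names,
        raw.mean(axis=0),
        raw.std(axis=0),
        norm.mean(axis=0),
        norm.std(axis=0),
        k=k,
    )


@dataclass
class AssignmentResult:
    """Identity call for one ROI: hit set, winner-take-all primary, secondaries."""

    roi_id: str
    hits: set[str]
    primary: str | None
    secondaries: tuple[str, ...]
    pass_id: int
    zscores: dict[str, float]

    def identities(self) -> set[str]:
        return ({self.primary} if self.primary else set()) | set(self.secondaries)


@dataclass
class ShareProfile:
    """Per-fluorophore beta contribution as percent of total."""

    fluorophores: tuple[str, ...]
    shares: np.ndarray  # percent, sums to 100
    source: str = "experimental"

    def __post_init__(self):
        self.shares = np.asarray(self.shares, dtype=float)
        if np.any(self.shares < 0):
            raise ValueError("shares must be nonnegative")
        total = self.shares.sum()
        if total <= 0:
            raise ValueError("shares must have positive total")
        self.shares = 100.0 * self.shares / total

    @classmethod
    def equal(cls, fluorophores) -> "ShareProfile":
        """Theoretical equal distribution: an ideal dataset with equal counts of
        pure single-fluorophore ROIs yields identical per-fluorophore totals."""
        names = tuple(fluorophores)
        return cls(names, np.full(len(names), 100.0 / len(names)), "theoretical_equal")

    @classmethod
    def from_betas(cls, betas: list[BetaVector], fluorophores=None, source="experimental"):
        names = tuple(fluorophores) if fluorophores is not None else betas[0].fluorophores
        idx = [betas[0].fluorophores.index(n) for n in names]
        totals = np.stack([b.beta_raw for b in betas]).sum(axis=0)[idx]
        if totals.sum() <= 0:
            totals = np.ones(len(names))
        return cls(names, totals, source)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.fluorophores, self.shares))


def _assign(
    beta: BetaVector,
    baseline: BaselineStats,
    cutoff_raw: np.ndarray,
    cutoff_norm: np.ndarray,
    assignable: np.ndarray,
    pass_id: int,
) -> AssignmentResult:
    z_raw, z_norm = baseline.zscores(beta)
    z_best = np.maximum(z_raw, z_norm)
    hit = assignable & (
        (beta.beta_raw > cutoff_raw) | (beta.beta_norm > cutoff_norm)
    )
    names = np.asarray(beta.fluorophores)
    hit_idx = np.nonzero(hit)[0]
    if hit_idx.size:
        order = hit_idx[np.argsort(-z_best[hit_idx], kind="stable")]
        primary = str(names[order[0]])
        secondaries = tuple(str(n) for n in names[order[1:]])
    else:
        primary, secondaries = None, ()
    return AssignmentResult(
        beta.roi_id,
        {str(n) for n in names[hit_idx]},
        primary,
        secondaries,
        pass_id,
        dict(zip(beta.fluorophores, z_best)),
    )


def _assignable_mask(fluorophores, assignable) -> np.ndarray:
    if assignable is None:
        return np.ones(len(fluorophores), dtype=bool)
    allowed = set(assignable)
    unknown = allowed - set(fluorophores)
    if unknown:
        raise ValueError(f"assignable names not in library: {sorted(unknown)}")
    return np.array([n in allowed for n in fluorophores])


def single_pass_assign(
    beta: BetaVector,
    baseline: BaselineStats,
    assignable=None,
) -> AssignmentResult:
    """First-pass rule: hit iff beta_raw or beta_norm exceeds its mean + k*SD cutoff."""
    mask = _assignable_mask(beta.fluorophores, assignable)
    return _assign(
        beta, baseline, baseline.cutoff_raw, baseline.cutoff_norm, mask, pass_id=1
    )


def adjusted_cutoffs(
    baseline: BaselineStats,
    theoretical: ShareProfile,
    experimental: ShareProfile,
) -> tuple[np.ndarray, np.ndarray]:
    """Second-pass cutoffs: SD term divided by the over-representation ratio.

    For each fluorophore r = experimental_share / theoretical_share; when
    r > 1 the cutoff becomes mean + k*SD/r (proportionally lowered threshold
    for over-represented fluorophores), otherwise it is unchanged.  This is
    the one concrete realization of the proportional adjustment and is kept
    isolated here for substitution.
    """
    theo_map = theoretical.as_dict()
    exp_map = experimental.as_dict()
    if any(v <= 0 for v in theo_map.values()):
        raise ValueError("theoretical share must be positive for every fluorophore")
    # fluorophores outside the share profiles (e.g. a non-assignable indicator)
    # keep their first-pass cutoff
    ratio = np.array(
        [
            exp_map.get(n, 0.0) / theo_map[n] if n in theo_map else 0.0
            for n in baseline.fluorophores
        ]
    )
    with np.errstate(divide="ignore"):
        damp = np.where(ratio > 1.0, 1.0 / np.maximum(ratio, 1e-300), 1.0)
    cut_raw = baseline.mean_raw + baseline.k * baseline.sd_raw * damp
    cut_norm = baseline.mean_norm + baseline.k * baseline.sd_norm * damp
    return cut_raw, cut_norm


def dual_pass_assign(
    unassigned: list[BetaVector],
    baseline: BaselineStats,
    theoretical: ShareProfile,
    experimental: ShareProfile,
    assignable=None,
) -> list[AssignmentResult]:
    """Re-evaluate pass-1 no-hit ROIs with adjusted cutoffs (pass_id = 2)."""
    cut_raw, cut_norm = adjusted_cutoffs(baseline, theoretical, experimental)
    if not unassigned:
        return []
    mask = _assignable_mask(unassigned[0].fluorophores, assignable)
    return [
        _assign(b, baseline, cut_raw, cut_norm, mask, pass_id=2) for b in unassigned
    ]


class SpectralUnmixer:
    """Per-subject identity classifier built from ROI spectra and a reference library.

    Parameters
    ----------
    spectra
        The subject's ROI fingerprints (>= 2).
    library
        :class:`~fluomux.spectral.ReferenceLibrary` including GCaMP.
    k
        SD multiplier of the hit cutoff (default 1.5).
    dual_pass
        Re-evaluate pass-1 no-hits with prevalence-adjusted thresholds.
    assignable
        Fluorophore names eligible for identity assignment.  Defaults to all
        library members; in vivo the calcium indicator is fit (to absorb its
        signal) but excluded from assignment.
    theoretical_shares
        Reference equal-distribution share profile for the dual pass; defaults
        to exact equal shares over the assignable fluorophores.
    nonnegative
        Constrain betas >= 0 (NNLS).  Unconstrained least squares available
        for comparison.
    """

    def __init__(
        self,
        spectra: list[Fingerprint],
        library: ReferenceLibrary,
        k: float = 1.5,
        dual_pass: bool = True,
        assignable=None,
        theoretical_shares: ShareProfile | None = None,
        nonnegative: bool = True,
    ):
        if len(spectra) < 2:
            raise ValueError("classification requires at least two ROIs")
        self.spectra = list(spectra)
        self.library = library
        self.k = k
        self.dual_pass = dual_pass
        self.assignable = (
            tuple(assignable) if assignable is not None else tuple(library.names)
        )
        self.theoretical_shares = theoretical_shares or ShareProfile.equal(
            self.assignable
        )
        self.nonnegative = nonnegative

    def fit(self) -> "UnmixResults":
        betas = fit_betas_many(self.spectra, self.library, nonnegative=self.nonnegative)
        baseline = compute_baseline(betas, k=self.k)
        experimental = ShareProfile.from_betas(betas, self.assignable)
        pass1 = [single_pass_assign(b, baseline, self.assignable) for b in betas]
        assignments = {a.roi_id: a for a in pass1}
        if self.dual_pass:
            unassigned = [b for b, a in zip(betas, pass1) if not a.hits]
            for a in dual_pass_assign(
                unassigned,
                baseline,
                self.theoretical_shares,
                experimental,
                self.assignable,
            ):
                assignments[a.roi_id] = a
        ordered = [assignments[b.roi_id] for b in betas]
        return UnmixResults(
            self, betas, baseline, ordered, experimental, self.theoretical_shares
        )


@dataclass
class UnmixResults:
    """Fitted unmixing results for one subject."""

    model: SpectralUnmixer
    betas: list[BetaVector]
    baseline: BaselineStats
    assignments: list[AssignmentResult]
    experimental_shares: ShareProfile
    theoretical_shares: ShareProfile

    @property
    def n_rois(self) -> int:
        return len(self.betas)

    def assignment_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.assignments:
            key = a.primary or "no match"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def match_rate(self) -> float:
        """Fraction of ROIs given a primary identity (either pass)."""
        return sum(a.primary is not None for a in self.assignments) / self.n_rois

    def to_frame(self) -> pd.DataFrame:
        """Per-ROI assignment table with betas and z-scores per fluorophore."""
        rows = []
        for b, a in zip(self.betas, self.assignments):
            row = {
                "roi_id": b.roi_id,
                "pass": a.pass_id,
                "primary": a.primary or "",
                "secondaries": ";".join(a.secondaries),
                "residual": b.residual,
            }
            for i, name in enumerate(b.fluorophores):
                row[f"beta_raw_{name}"] = b.beta_raw[i]
                row[f"beta_norm_{name}"] = b.beta_norm[i]
                row[f"z_{name}"] = a.zscores[name]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        counts = self.assignment_counts()
        pass2 = sum(
            1 for a in self.assignments if a.pass_id == 2 and a.primary is not None
        )
        lines = [
            "Spectral unmixing results",
            "=" * 60,
            f"ROIs: {self.n_rois}    matched: {self.match_rate():.1%}"
            f"    (pass 2 recoveries: {pass2})",
            f"cutoff: mean + {self.baseline.k} SD per fluorophore, raw OR norm channel",
            "",
            f"{'fluorophore':<14}{'n primary':>10}{'share %':>10}"
            f"{'cutoff_raw':>12}{'cutoff_norm':>12}",
            "-" * 60,
        ]
        shares = self.experimental_shares.as_dict()
        for i, name in enumerate(self.baseline.fluorophores):
            lines.append(
                f"{name:<14}{counts.get(name, 0):>10}"
                f"{shares.get(name, float('nan')):>10.1f}"
                f"{self.baseline.cutoff_raw[i]:>12.4f}"
                f"{self.baseline.cutoff_norm[i]:>12.4f}"
            )
        lines.append(f"{'no match':<14}{counts.get('no match', 0):>10}")
        return "\n".join(lines)

    def plot_betas(self, roi_id: str, ax=None):
        """Bar plot of one ROI's raw betas against the subject baseline."""
        import matplotlib.pyplot as plt

        idx = [b.roi_id for b in self.betas].index(roi_id)
        b = self.betas[idx]
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(b.fluorophores))
        ax.bar(x, b.beta_raw, label="beta_raw")
        ax.plot(x, self.baseline.cutoff_raw, "k--", label="cutoff (mean+kSD)")
        ax.set_xticks(x, b.fluorophores, rotation=60, ha="right")
        ax.set_ylabel("beta")
        ax.set_title(f"ROI {roi_id}")
        ax.legend()
        return ax


def classify_subject(
    spectra: list[Fingerprint],
    library: ReferenceLibrary,
    k: float = 1.5,
    dual_pass: bool = True,
    assignable=None,
    theoretical_shares: ShareProfile | None = None,
    nonnegative: bool = True,
) -> UnmixResults:
    """Fit betas, compute the baseline, and assign identities for one subject."""
    return SpectralUnmixer(
        spectra,
        library,
        k=k,
        dual_pass=dual_pass,
        assignable=assignable,
        theoretical_shares=theoretical_shares,
        nonnegative=nonnegative,
    ).fit()
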