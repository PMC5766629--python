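"""¹H-NMR spectral preprocessing and differential-metabolite calling.

The workflow mirrors standard NMR metabolomics practice: processed
spectra on a fine chemical-shift grid are bucketed into fixed 0.01-ppm
bins over δ 0.50–9.00, the residual-water region δ 4.5–5.0 is excluded,
rows are normalized to unit total intensity, and, after a supervised
latent-variable model is fitted (:mod:`netpharm.latent`), metabolites
are called differential when their assigned bins carry VIP ≥ 1 and a
two-group t-test is significant.  Fold changes are reported as a
magnitude ≥ 1 plus an up/down direction for treated vs control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .latent import PLSDAResults

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumSet",
    "BinnedMatrix",
    "DifferentialMetabolite",
    "bin_spectra",
    "normalize_rows",
    "call_differential",
    "read_spectra_csv",
    "read_groups_tsv",
]

DEFAULT_RANGE = (0.50, 9.00)
DEFAULT_WIDTH = 0.01
DEFAULT_EXCLUDE = ((4.5, 5.0),)
_EPS = 1e-9


@dataclass
class SpectrumSet:
    """Processed 1D spectra on a common chemical-shift grid.

    ``ppm`` is strictly monotone (conventionally descending, high field
    to the right); ``intensities`` is samples x grid and non-negative.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, float)
        self.intensities = np.asarray(self.intensities, float)
        self.groups = np.asarray(self.groups)
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm grid must be strictly monotone")
        if self.intensities.shape != (len(self.sample_ids), self.ppm.size):
            raise ValueError("intensities must be samples x grid")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label per sample required")


@dataclass
class BinnedMatrix:
    """Bucketed spectra: samples x retained 0.01-ppm bins.

    ``bin_left`` holds the left (lower-ppm) edge of each retained
    half-open bin [left, left + width); bins overlapping any excluded
    interval were dropped before normalization.
    """

    bin_left: np.ndarray
    width: float
    excluded: tuple[tuple[float, float], ...]
    X: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray
    normalized: bool = False

    @property
    def n_bins(self) -> int:
        return self.bin_left.size

    def bin_index(self, ppm: float) -> int | None:
        """Index of the retained bin containing ``ppm`` (None if the
        shift falls in an excluded or out-of-range region)."""
        idx = np.flatnonzero(
            (self.bin_left - _EPS <= ppm) & (ppm < self.bin_left + self.width - _EPS)
        )
        return int(idx[0]) if idx.size else None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{l:.2f}" for l in self.bin_left]
        return pd.DataFrame(self.X, index=self.sample_ids, columns=cols)


def _intervals_overlap(l: float, r: float, lo: float, hi: float) -> bool:
    # half-open [l, r) vs [lo, hi): nonempty intersection
    return l < hi - _EPS and lo < r - _EPS


def bin_spectra(
    spectra: SpectrumSet,
    width: float = DEFAULT_WIDTH,
    ppm_range: tuple[float, float] = DEFAULT_RANGE,
    exclude: Sequence[tuple[float, float]] = DEFAULT_EXCLUDE,
) -> BinnedMatrix:
    """Bucket spectra into fixed-width bins and drop excluded regions.

    Each bin [left, left + width) accumulates the grid intensities whose
    chemical shift falls inside it.  With the defaults (0.01 ppm over
    [0.50, 9.00), water region [4.5, 5.0) excluded) this yields 850 raw
    bins of which 800 are retained.  Exclusion happens *before* any
    normalization so residual water never distorts row sums.
    """
    lo, hi = ppm_range
    if width <= 0:
        raise ValueError("bin width must be positive")
    pmin, pmax = spectra.ppm.min(), spectra.ppm.max()
    if pmin > lo + _EPS or pmax < hi - width - _EPS:
        raise ValueError(
            f"spectra cover [{pmin:g}, {pmax:g}] but binning requests "
            f"[{lo:g}, {hi:g}): uncovered span"
        )
    n_raw = int(round((hi - lo) / width))
    lefts = np.round(lo + width * np.arange(n_raw), 10)

    idx = np.floor((spectra.ppm - lo) / width + _EPS).astype(int)
    in_range = (idx >= 0) & (idx < n_raw) & (spectra.ppm >= lo - _EPS)
    Xraw = np.zeros((len(spectra.sample_ids), n_raw))
    np.add.at(Xraw.T, idx[in_range], spectra.intensities[:, in_range].T)

    keep = np.array(
        [
            not any(_intervals_overlap(l, l + width, elo, ehi) for elo, ehi in exclude)
            for l in lefts
        ]
    )
    return BinnedMatrix(
        bin_left=lefts[keep],
        width=width,
        excluded=tuple(tuple(e) for e in exclude),
        X=Xraw[:, keep],
        sample_ids=list(spectra.sample_ids),
        groups=spectra.groups.copy(),
        normalized=False,
    )


def normalize_rows(binned: BinnedMatrix) -> BinnedMatrix:
    """Normalize each sample (row) to unit total intensity.

    Raises if any row has a non-positive sum, naming the sample.
    """
    sums = binned.X.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(
            f"sample {binned.sample_ids[bad[0]]!r} has non-positive total "
            "intensity; cannot normalize"
        )
    return replace(binned, X=binned.X / sums[:, None], normalized=True)


# ---------------------------------------------------------------------
# differential metabolites
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentialMetabolite:
    """A metabolite called as altered between treated and control.

    ``fold_change`` is the magnitude (ratio of the larger group mean
    over the smaller, always >= 1) and ``direction`` records whether the
    treated group is higher ("up") or lower ("down")."""

    name: str
    direction: Literal["up", "down"]
    fold_change: float
    p: float
    vip: float
    compartment: str = ""


def call_differential(
    binned: BinnedMatrix,
    assignments: Mapping[str, Iterable[float]],
    results: PLSDAResults,
    vip_min: float = 1.0,
    alpha: float = 0.05,
    control_label: str | None = None,
    welch: bool = False,
    compartment: str = "",
) -> list[DifferentialMetabolite]:
    """Call differential metabolites from assigned bins.

    Parameters
    ----------
    binned
        Normalized binned matrix with exactly two group labels.
    assignments
        Map metabolite name -> chemical shifts (ppm) of its assigned
        resonances; each shift is mapped to the retained bin containing
        it.  Metabolites whose shifts all fall in excluded/out-of-range
        regions are skipped with a warning.
    results
        A fitted PLS-DA/OPLS-DA results object on the same matrix,
        providing per-bin VIP values.
    vip_min, alpha
        A metabolite is called when the max VIP over its assigned bins
        is >= ``vip_min`` and the two-sided t-test p-value is < ``alpha``.
    control_label
        Which group label is the control; defaults to the
        lexicographically smaller label.
    welch
        Use Welch's unequal-variance t-test instead of Student's.
    """
    if len(results.vip) != binned.n_bins:
        raise ValueError("model was not fitted on this binned matrix")
    labels = np.unique(binned.groups)
    if labels.size != 2:
        raise ValueError("need exactly two groups")
    ctrl = control_label if control_label is not None else sorted(map(str, labels))[0]
    is_ctrl = binned.groups.astype(str) == str(ctrl)
    if not is_ctrl.any() or is_ctrl.all():
        raise ValueError(f"control label {ctrl!r} does not split the samples")

    out: list[DifferentialMetabolite] = []
    for name, shifts in assignments.items():
        bins = [binned.bin_index(s) for s in shifts]
        bins = sorted({b for b in bins if b is not None})
        if not bins:
            logger.warning(
                "metabolite %r has no assigned bins in the retained regions; skipped",
                name,
            )
            continue
        intensity = binned.X[:, bins].sum(axis=1)
        a, b = intensity[~is_ctrl], intensity[is_ctrl]  # treated, control
        t_p = stats.ttest_ind(a, b, equal_var=not welch).pvalue
        vip = float(results.vip[bins].max())
        m_t, m_c = a.mean(), b.mean()
        direction = "up" if m_t > m_c else "down"
        denom = min(m_t, m_c)
        fc = float(max(m_t, m_c) / denom) if denom > 0 else np.inf
        if vip >= vip_min and t_p < alpha:
            out.append(
                DifferentialMetabolite(
                    name=name, direction=direction, fold_change=fc,
                    p=float(t_p), vip=vip, compartment=compartment,
                )
            )
    return out


def differential_to_frame(calls: list[DifferentialMetabolite]) -> pd.DataFrame:
    """Tabulate calls in the up/down-arrow + magnitude convention."""
    return pd.DataFrame(
        [
            {
                "metabolite": c.name,
                "compartment": c.compartment,
                "direction": "↑" if c.direction == "up" else "↓",
                "fold_change": round(c.fold_change, 2),
                "p": c.p,
                "vip": round(c.vip, 3),
            }
            for c in calls
        ]
    )


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------


def read_spectra_csv(
    path: str | Path, groups: Mapping[str, str] | str | Path
) -> SpectrumSet:
    """Read spectra from CSV (first column ppm, one column per sample)
    plus a sample -> group mapping (dict or sidecar TSV path)."""
    df = pd.read_csv(path)
    ppm = df.iloc[:, 0].to_numpy(float)
    sample_ids = list(df.columns[1:])
    if isinstance(groups, (str, Path)):
        groups = read_groups_tsv(groups)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValueError(f"no group label for sample(s) {missing}")
    return SpectrumSet(
        ppm=ppm,
        intensities=df.iloc[:, 1:].to_numpy(float).T,
        sample_ids=sample_ids,
        groups=np.array([groups[s] for s in sample_ids]),
    )


def write_spectra_csv(spectra: SpectrumSet, path: str | Path) -> None:
    df = pd.DataFrame(
        spectra.intensities.T, columns=spectra.sample_ids
    )
    df.insert(0, "ppm", spectra.ppm)
    df.to_csv(path, index=False, float_format="%.8g")


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample ID, group label."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected sample<TAB>group")
        out[fields[0].strip()] = fields[1].strip()
    return out
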