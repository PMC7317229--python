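"""Single-channel cell-attached patch analysis.

The pipeline behind the group summary table: junction-potential
correction, half-amplitude idealization of sweeps, channel counting from
simultaneous open levels, NPo/N open-probability estimation from >= 20
sweeps at −6.7 mV, seal-area estimation from pipette resistance,
occurrence and channel-density aggregation per group x microdomain, and
OLS conductance fitting of single-channel I-V data.

Sign convention: inward current is negative in storage; idealization
works on magnitudes; conductances are reported positive.  Internal
arithmetic is unrounded; two-decimal (density) / one-decimal (occurrence)
rounding is presentation only.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ltccmicro.protocols import correct_junction_potential  # noqa: F401  (re-export)
from ltccmicro.synth.iv import IVDataset
from ltccmicro.synth.sweeps import SweepSet

__all__ = [
    "SealRecord",
    "GroupSummary",
    "ConductanceFit",
    "correct_junction_potential",
    "idealize_sweep",
    "idealize_sweep_set",
    "count_channel_levels",
    "estimate_open_probability",
    "seal_area_from_resistance",
    "fit_unitary_conductance",
    "summarize_group",
    "pool_groups",
    "load_table1_counts",
    "load_reported_group_stats",
    "table1_from_counts",
    "analyze_seal",
    "GROUPS",
    "MICRODOMAINS",
    "SEAL_AREA_CONSTANT",
    "MIN_PO_SWEEPS",
]

GROUPS = ("Control", "ICM", "ICM+LVAD", "DCM", "DCM+LVAD", "BayK", "Myo+LVAD")
MICRODOMAINS = ("TT", "Crest")

#: Minimum number of analyzable sweeps required before a Po is reported.
MIN_PO_SWEEPS = 20

#: Seal area model area = C / R^2 (µm²·MΩ²).  C reproduces the grand mean
#: area per seal (43.56 µm² over 304 seals ≈ 0.1433 µm²) at the stated
#: mean pipette resistance of 27.78 MΩ.
SEAL_AREA_CONSTANT = 110.6

#: Events shorter than this are removed by the idealizer (≈ the rise time
#: of the 2 kHz acquisition filter), ms.
MIN_EVENT_MS = 0.3


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class SealRecord:
    """One cell-attached seal: metadata plus derived per-seal quantities."""

    seal_id: str
    group: str
    microdomain: str
    pipette_resistance: float  # MΩ
    area: float | None = None  # µm²
    has_activity: bool = False
    n_channels: int = 0
    po: float | None = None
    conductance: float | None = None  # pS
    exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.microdomain not in MICRODOMAINS:
            raise ValueError(f"unknown microdomain {self.microdomain!r}")
        if self.area is None:
            self.area = seal_area_from_resistance(self.pipette_resistance)
        if self.has_activity != (self.n_channels >= 1):
            raise ValueError("has_activity must match n_channels >= 1")


@dataclass
class GroupSummary:
    """Aggregate of one group x microdomain stratum (one table row)."""

    group: str
    microdomain: str
    n_seals: int
    n_active: int
    total_area: float  # µm²
    total_channels: int
    po_values: tuple[float, ...] = ()

    @property
    def occurrence(self) -> float:
        """Percent of seals showing LTCC activity."""
        return 100.0 * self.n_active / self.n_seals

    @property
    def density(self) -> float:
        """Channels per µm² of total sealed area (all seals)."""
        return self.total_channels / self.total_area

    @property
    def mean_channels_per_active_seal(self) -> float | None:
        if self.n_active == 0:
            return None
        return self.total_channels / self.n_active

    @property
    def mean_po(self) -> float | None:
        return float(np.mean(self.po_values)) if self.po_values else None

    @property
    def sem_po(self) -> float | None:
        if len(self.po_values) < 2:
            return None
        return float(np.std(self.po_values, ddof=1) / math.sqrt(len(self.po_values)))

    def as_row(self) -> dict:
        """Presentation row with the table's rounding conventions."""
        mean_ch = self.mean_channels_per_active_seal
        return {
            "group": self.group,
            "microdomain": self.microdomain,
            "n_seals": self.n_seals,
            "occurrence_pct": _round_half_up(self.occurrence, 1),
            "total_area_um2": round(self.total_area, 2),
            "total_channels": self.total_channels,
            "mean_channels_per_active_seal": (
                _round_half_up(mean_ch, 2) if mean_ch is not None else np.nan
            ),
            "density_per_um2": _round_half_up(self.density, 2),
        }


@dataclass
class ConductanceFit:
    """OLS fit of mean open amplitude (pA) against test potential (mV)."""

    voltages: np.ndarray
    mean_open_amplitudes: np.ndarray
    slope: float  # pS, positive
    slope_se: float  # pS
    reversal_estimate: float  # mV
    r_squared: float


def _round_half_up(x: float, ndigits: int) -> float:
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Idealization and Po
# ---------------------------------------------------------------------------

def idealize_sweep(
    sweep: np.ndarray,
    unitary_amplitude: float,
    sampling_rate: float,
    n_levels_max: int = 5,
    baseline_window: tuple[int, int] | None = None,
    min_event_ms: float = MIN_EVENT_MS,
    max_baseline_drift: float = 0.5,
) -> np.ndarray:
    """Idealize one current sweep to a per-sample integer open count.

    Baseline (median of the pre-pulse window) is subtracted, the trace is
    divided by the unitary amplitude and open counts are assigned by
    half-amplitude threshold crossings at k − 1/2 level boundaries.
    Events (openings or gaps) shorter than ``min_event_ms`` are removed,
    shortest first, mirroring the manual rejection of filter-limited
    spikes.

    Raises
    ------
    ValueError
        If the baseline drifts by more than ``max_baseline_drift`` times
        the unitary amplitude across the sweep (seal flagged unusable).
    """
    if unitary_amplitude == 0:
        raise ValueError("unitary_amplitude must be non-zero")
    sweep = np.asarray(sweep, dtype=float)
    if baseline_window is None:
        baseline_window = (0, max(int(0.02 * sweep.size), 8))
    b0, b1 = baseline_window
    baseline = float(np.median(sweep[b0:b1])) if b1 > b0 else 0.0
    tail = sweep[-max(b1 - b0, 8):]
    drift = abs(float(np.median(tail)) - baseline)
    if drift > max_baseline_drift * abs(unitary_amplitude):
        raise ValueError("unresolvable baseline drift; sweep unusable")
    # magnitudes: normalize so one open channel sits at +1
    x = (sweep - baseline) / unitary_amplitude
    levels = np.clip(np.floor(x + 0.5).astype(int), 0, n_levels_max)
    return _remove_brief_events(levels, min_samples=int(round(min_event_ms * 1e-3 * sampling_rate)))


def _remove_brief_events(levels: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge runs shorter than ``min_samples`` into their neighbours."""
    if min_samples <= 1 or levels.size == 0:
        return levels
    out = levels.copy()
    changed = True
    while changed:
        changed = False
        # run-length encode
        idx = np.flatnonzero(np.diff(out)) + 1
        starts = np.concatenate(([0], idx))
        ends = np.concatenate((idx, [out.size]))
        lengths = ends - starts
        if len(starts) <= 1:
            break
        order = np.argsort(lengths, kind="stable")
        for k in order:
            if lengths[k] >= min_samples:
                break
            s, e = starts[k], ends[k]
            left = out[s - 1] if s > 0 else None
            right = out[e] if e < out.size else None
            if left is None and right is None:
                continue
            if left is None:
                fill = right
            elif right is None:
                fill = left
            else:
                # absorb into the longer neighbouring run
                fill = left if lengths[k - 1] >= lengths[k + 1] else right
            out[s:e] = fill
            changed = True
            break
    return out


def idealize_sweep_set(
    sweeps: SweepSet,
    n_levels_max: int = 5,
    **kw,
) -> tuple[np.ndarray, list[int]]:
    """Idealize every sweep of a set over its full duration.

    Returns ``(idealized, excluded)`` where ``idealized`` is
    (n_usable, n_samples) and ``excluded`` the indices of rejected sweeps.
    """
    fs = sweeps.sampling_rate
    a, _ = sweeps.step_window()
    baseline_window = (0, max(a - int(0.002 * fs), 8))
    rows, excluded = [], []
    for i in range(sweeps.n_sweeps):
        try:
            rows.append(
                idealize_sweep(
                    sweeps.current[i],
                    sweeps.unitary_amplitude,
                    fs,
                    n_levels_max=n_levels_max,
                    baseline_window=baseline_window,
                    **kw,
                )
            )
        except ValueError:
            excluded.append(i)
    return np.array(rows, dtype=int), excluded


def count_channel_levels(idealized: np.ndarray) -> int:
    """Number of channels in the seal: the maximum simultaneous open count.

    A single observed level means one channel; this is a lower bound on
    the true channel count and reaches it for sufficiently long records.
    Returns 0 for a fully quiescent record.
    """
    if idealized.size == 0:
        return 0
    return int(idealized.max())


def estimate_open_probability(
    idealized: np.ndarray,
    n_channels: int,
    step_window: tuple[int, int],
    sampling_rate: float | None = None,
    edge_blank_ms: float = 5.0,
) -> float:
    """Single-channel Po as NPo/N over the depolarizing step.

    ``idealized`` is (n_sweeps, n_samples).  The mean summed open fraction
    across sweeps is divided by the channel count; the first
    ``edge_blank_ms`` after the capacitive edge are excluded.  At least
    20 analyzable sweeps are required (the protocol floor).
    """
    if idealized.ndim != 2:
        raise ValueError("idealized must be 2D (sweeps x samples)")
    if idealized.shape[0] < MIN_PO_SWEEPS:
        raise ValueError(
            f"Po requires at least {MIN_PO_SWEEPS} analyzable sweeps, got {idealized.shape[0]}"
        )
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    a, b = step_window
    if sampling_rate is not None:
        a += int(round(edge_blank_ms * 1e-3 * sampling_rate))
    npo = idealized[:, a:b].mean(axis=1)  # summed open fraction per sweep
    po = float(npo.mean() / n_channels)
    return min(max(po, 0.0), 1.0)


def analyze_seal(
    sweeps: SweepSet,
    seal_id: str,
    group: str,
    microdomain: str,
    pipette_resistance: float,
) -> SealRecord:
    """Full per-seal pipeline: idealize, count channels, Po, seal area."""
    idealized, excluded = idealize_sweep_set(sweeps)
    n_ch = count_channel_levels(idealized) if idealized.size else 0
    rec = SealRecord(
        seal_id=seal_id,
        group=group,
        microdomain=microdomain,
        pipette_resistance=pipette_resistance,
        has_activity=n_ch >= 1,
        n_channels=n_ch,
        exclusions=[f"sweep {i}: baseline drift" for i in excluded],
    )
    if n_ch >= 1 and idealized.shape[0] >= MIN_PO_SWEEPS:
        rec.po = estimate_open_probability(
            idealized, n_ch, sweeps.step_window(), sweeps.sampling_rate
        )
    return rec


# ---------------------------------------------------------------------------
# Seal area and conductance
# ---------------------------------------------------------------------------

def seal_area_from_resistance(r_pipette: float, constant: float = SEAL_AREA_CONSTANT) -> float:
    """Membrane area under the pipette (µm²) from pipette resistance (MΩ).

    Inverse-square tip-geometry law ``area = C / R²``; strictly decreasing
    in resistance, calibrated so the mean pipette resistance (27.78 MΩ)
    maps to the tabulated grand-mean area per seal (≈0.143 µm²).
    """
    if r_pipette <= 0:
        raise ValueError("pipette resistance must be positive")
    return constant / r_pipette**2


def fit_unitary_conductance(iv: IVDataset) -> ConductanceFit:
    """OLS line through mean open amplitudes vs test potential.

    Slope (pA/mV = nS) is reported in pS; the reversal potential is the
    x-intercept.
    """
    vs, means = iv.mean_by_voltage()
    if vs.size < 3:
        raise ValueError("conductance fit requires at least 3 distinct voltages")
    if np.ptp(vs) == 0:
        raise ValueError("zero voltage spread")
    A = np.vstack([vs, np.ones_like(vs)]).T
    coef, res, *_ = np.linalg.lstsq(A, means, rcond=None)
    slope_ns, intercept = coef  # pA/mV = nS
    pred = A @ coef
    ss_res = float(((means - pred) ** 2).sum())
    ss_tot = float(((means - means.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = vs.size - 2
    if dof > 0 and ss_res > 0:
        s2 = ss_res / dof
        slope_se = math.sqrt(s2 / float(((vs - vs.mean()) ** 2).sum()))
    else:
        slope_se = 0.0
    return ConductanceFit(
        voltages=vs,
        mean_open_amplitudes=means,
        slope=slope_ns * 1e3,
        slope_se=slope_se * 1e3,
        reversal_estimate=float(-intercept / slope_ns) if slope_ns != 0 else math.nan,
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def summarize_group(
    records: Iterable[SealRecord],
    group: str,
    microdomain: str,
) -> GroupSummary:
    """Aggregate the seals of one group x microdomain stratum."""
    sel = [r for r in records if r.group == group and r.microdomain == microdomain]
    if not sel:
        raise ValueError(f"no seals in stratum {group}/{microdomain}")
    return GroupSummary(
        group=group,
        microdomain=microdomain,
        n_seals=len(sel),
        n_active=sum(r.has_activity for r in sel),
        total_area=float(sum(r.area for r in sel)),
        total_channels=int(sum(r.n_channels for r in sel)),
        po_values=tuple(r.po for r in sel if r.po is not None),
    )


def pool_groups(
    summaries: Sequence[GroupSummary],
    label: str = "pooled",
    allow_mixed_microdomains: bool = False,
) -> GroupSummary:
    """Pool strata by summing counts and areas before taking ratios.

    Pooled occurrence/density/mean-channels are ratios of summed counts,
    never means of per-stratum ratios.
    """
    if not summaries:
        raise ValueError("nothing to pool")
    domains = {s.microdomain for s in summaries}
    if len(domains) > 1 and not allow_mixed_microdomains:
        raise ValueError("refusing to pool across microdomains without explicit override")
    po: tuple[float, ...] = ()
    for s in summaries:
        po = po + s.po_values
    return GroupSummary(
        group=label,
        microdomain=domains.pop() if len(domains) == 1 else "mixed",
        n_seals=sum(s.n_seals for s in summaries),
        n_active=sum(s.n_active for s in summaries),
        total_area=sum(s.total_area for s in summaries),
        total_channels=sum(s.total_channels for s in summaries),
        po_values=po,
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("ltccmicro") / "data" / name


def load_table1_counts() -> pd.DataFrame:
    """The packaged per-stratum counts behind the published summary table."""
    with importlib.resources.as_file(_data_path("table1_counts.csv")) as p:
        return pd.read_csv(p)


def load_reported_group_stats() -> pd.DataFrame:
    """Published group statistics (Po means ± SEM, conductances, image
    metrics).  These derive from the original patient recordings and are
    served for reporting/comparison only — nothing in the package claims
    to recompute them."""
    with importlib.resources.as_file(_data_path("reported_group_stats.csv")) as p:
        return pd.read_csv(p)


def table1_from_counts(counts: pd.DataFrame | None = None) -> list[GroupSummary]:
    """Build :class:`GroupSummary` rows from the counts fixture."""
    df = counts if counts is not None else load_table1_counts()
    out = []
    for _, row in df.iterrows():
        out.append(
            GroupSummary(
                group=row["group"],
                microdomain=row["microdomain"],
                n_seals=int(row["n_seals"]),
                n_active=int(row["n_active"]),
                total_area=float(row["total_area_um2"]),
                total_channels=int(row["total_channels"]),
            )
        )
    return out


def failing_crest_pool(counts: pd.DataFrame | None = None) -> GroupSummary:
    """Pool of the four failing crest strata (ICM, ICM+LVAD, DCM, DCM+LVAD)."""
    rows = table1_from_counts(counts)
    failing = [
        s for s in rows
        if s.microdomain == "Crest" and s.group in ("ICM", "ICM+LVAD", "DCM", "DCM+LVAD")
    ]
    return pool_groups(failing, label="failing")
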