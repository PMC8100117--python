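"""Optical-tweezers force-extension analysis.

The tether is two dsDNA handles (extensible worm-like chain) in series with
the nascent protein: a folded domain of fixed end-to-end size plus the
disordered released residues, and after unfolding the full polypeptide,
both modelled with the Odijk inextensible WLC.  Springs in series share the
force, so extensions add.  Unfolding shows up as a sudden extension gain
(contour-length release) with a concurrent force drop; refolding as the
mirror image during relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import mannwhitneyu

from .units import KBT_PN_NM, NM_PER_AA

__all__ = [
    "TetherModel",
    "PullTrace",
    "TransitionEvent",
    "ForceStats",
    "odijk_extension",
    "ewlc_extension",
    "series_extension",
    "invert_force",
    "detect_transitions",
    "contour_length_change",
    "force_stats",
    "refolding_frequency",
    "fret_efficiency",
]


@dataclass
class TetherModel:
    """Elastic model of the DNA-handles + nascent-chain tether.

    Defaults: two 5 kbp handles (1.7 um each), P = 50 nm, S = 1200 pN; the
    unfolded polypeptide has P = 0.65 nm and 0.365 nm of contour per residue;
    the folded domain contributes a fixed 2.0 nm end-to-end size, and
    ``released_contour`` nm of disordered linker are under tension in both
    states.
    """

    P_dna: float = 50.0  # nm
    Lc_dna: float = 3400.0  # nm, both handles
    S_dna: float = 1200.0  # pN
    P_prot: float = 0.65  # nm
    contour_per_aa: float = NM_PER_AA  # nm per residue
    folded_size: float = 2.0  # nm, folded-domain end-to-end distance
    released_contour: float = 15.0  # nm of disordered linker, both states
    delta_Lc: float = 31.0 * NM_PER_AA  # nm gained on unfolding
    kbt: float = KBT_PN_NM

    def __post_init__(self) -> None:
        for name in ("P_dna", "Lc_dna", "S_dna", "P_prot", "contour_per_aa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PullTrace:
    """One or more pull/relax cycles of (time, extension, force) samples."""

    time: np.ndarray  # s
    extension: np.ndarray  # nm
    force: np.ndarray  # pN
    cycle: np.ndarray  # int id per sample
    direction: np.ndarray  # "pull" | "relax" per sample

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.cycle = np.asarray(self.cycle, dtype=int)
        self.direction = np.asarray(self.direction, dtype=object)
        for cyc in np.unique(self.cycle):
            t = self.time[self.cycle == cyc]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"time not strictly increasing in cycle {cyc}")

    def segment(self, cyc: int, direction: str) -> dict[str, np.ndarray]:
        m = (self.cycle == cyc) & (self.direction == direction)
        return {
            "time": self.time[m],
            "extension": self.extension[m],
            "force": self.force[m],
        }

    def cycles(self) -> np.ndarray:
        return np.unique(self.cycle)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "extension_nm": self.extension,
                "force_pN": self.force,
                "cycle": self.cycle,
                "direction": self.direction,
            }
        )


@dataclass
class TransitionEvent:
    """A detected unfolding or refolding rip."""

    cycle: int
    direction: str  # "unfold" | "refold"
    force: float  # pN at the event
    delta_Lc_nm: float
    delta_Lc_aa: float
    score: float  # jump size over threshold
    index: int  # sample index within the segment


@dataclass
class ForceStats:
    """Mean +/- SEM of event forces for one experimental group."""

    label: str
    mean: float
    sem: float
    n: int


def odijk_extension(F, P: float, Lc: float, kbt: float = KBT_PN_NM):
    """Inextensible worm-like chain at high force: x = Lc (1 - 1/2 sqrt(kBT/(F P))).

    Valid for F well above kBT/(4P), where the predicted extension is
    positive.  F in pN, lengths nm; rejects F <= 0 (the model diverges).
    """
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise ValueError("Odijk WLC requires positive force")
    out = Lc * (1.0 - 0.5 * np.sqrt(kbt / (F * P)))
    return float(out) if out.ndim == 0 else out


def ewlc_extension(F, P: float, Lc: float, S: float, kbt: float = KBT_PN_NM):
    """Extensible WLC (Odijk): x = Lc (1 - 1/2 sqrt(kBT/(F P)) + F/S)."""
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise ValueError("extensible WLC requires positive force")
    out = Lc * (1.0 - 0.5 * np.sqrt(kbt / (F * P)) + F / S)
    return float(out) if out.ndim == 0 else out


def _protein_contour(model: TetherModel, state: str) -> float:
    if state == "folded":
        return model.released_contour
    if state == "unfolded":
        return model.released_contour + model.delta_Lc
    raise ValueError(f"unknown tether state {state!r}; use 'folded' or 'unfolded'")


def series_extension(F, model: TetherModel, state: str = "folded"):
    """Total tether extension at force F: DNA handles + protein in series.

    Folded: eWLC(DNA) + folded-domain size + Odijk WLC of the released
    linker.  Unfolded: eWLC(DNA) + Odijk WLC of linker + unfolded domain.
    Series elements share the force, so extensions add.
    """
    x = ewlc_extension(F, model.P_dna, model.Lc_dna, model.S_dna, model.kbt)
    Lp = _protein_contour(model, state)
    if Lp > 0:
        x = x + odijk_extension(F, model.P_prot, Lp, model.kbt)
    if state == "folded":
        x = x + model.folded_size
    return x


def invert_force(
    extension: float,
    model: TetherModel,
    state: str = "folded",
    f_lo: float = 1e-3,
    f_hi: float = 200.0,
    tol: float = 1e-6,
) -> float:
    """Force at a given total extension (monotone root solve, tol 1e-6 pN)."""
    x_max = series_extension(f_hi, model, state)
    if extension >= x_max:
        raise ValueError(
            f"extension {extension:.1f} nm at or beyond the model maximum "
            f"{x_max:.1f} nm at {f_hi} pN"
        )
    x_min = series_extension(f_lo, model, state)
    if extension <= x_min:
        return f_lo
    return float(
        brentq(lambda F: series_extension(F, model, state) - extension, f_lo, f_hi, xtol=tol)
    )


def detect_transitions(
    trace: PullTrace,
    model: TetherModel,
    *,
    min_jump: float = 3.0,  # nm
    sigma_mult: float = 3.5,
    window: int = 48,
    fit_range: tuple[float, float] = (5.0, 35.0),
    min_force: float = 8.0,  # pN; below this the two states are within noise
) -> list[TransitionEvent]:
    """Find the first unfolding rip per pull and refolding rip per relax.

    Residual-based detector: the folded-state series model predicts the
    extension from the measured force; an unfolding event is the first sample
    where the median residual over the next ``window`` samples exceeds the
    one over the previous window by more than max(``sigma_mult`` sigma of the
    local noise, ``min_jump``), with a concurrent force drop, and where the
    post-event samples actually fit the unfolded-state model (this kills the
    false positives that sustained force-noise dips would otherwise produce,
    since those shift the residuals of both state models together).
    Relaxation segments are scanned for the mirror-image refold (extension
    loss, force jump).  Detection starts above ``min_force``, where the
    folded/unfolded extension separation exceeds the handle-compliance
    noise.  At most one event of each kind per cycle is reported (a single
    two-state domain).
    """
    events: list[TransitionEvent] = []
    for cyc in trace.cycles():
        for seg_dir, ev_dir in (("pull", "unfold"), ("relax", "refold")):
            seg = trace.segment(int(cyc), seg_dir)
            F, x = seg["force"], seg["extension"]
            if len(F) < 50:
                continue
            ok = F > max(fit_range[0], min_force)
            resid = np.full(len(F), np.nan)
            resid_u = np.full(len(F), np.nan)
            resid[ok] = x[ok] - series_extension(F[ok], model, "folded")
            resid_u[ok] = x[ok] - series_extension(F[ok], model, "unfolded")
            ev = _scan_jump(resid, F, ev_dir, window, sigma_mult, min_jump,
                            resid_u=resid_u)
            if ev is not None:
                idx, jump, f_at = ev
                dLc = jump if ev_dir == "unfold" else -abs(jump)
                events.append(
                    TransitionEvent(
                        cycle=int(cyc),
                        direction=ev_dir,
                        force=f_at,
                        delta_Lc_nm=float(dLc),
                        delta_Lc_aa=float(dLc / model.contour_per_aa),
                        score=float(abs(jump)),
                        index=int(idx),
                    )
                )
    return events


def _scan_jump(resid, F, ev_dir, window, sigma_mult, min_jump, resid_u=None):
    """First index where the windowed residual jump crosses threshold.

    The noise floor is estimated locally (rolling median absolute
    difference): at low force the handles' compliance turns small force
    noise into large extension residuals, so a global threshold would
    either drown there or go blind at high force.
    """
    n = len(resid)
    diffs = np.abs(np.diff(resid))
    sign = 1.0 if ev_dir == "unfold" else -1.0
    half = 40
    for i in range(window, n - 8):
        pre = resid[i - window : i]
        post = resid[i : min(i + window, n)]  # shrinks near the segment end
        if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
            continue
        lo, hi = max(0, i - half), min(len(diffs), i + half)
        local = diffs[lo:hi]
        local = local[np.isfinite(local)]
        if local.size < 10:
            continue
        sigma_local = 1.4826 * float(np.median(local)) / np.sqrt(2.0)
        # 1.25 sigma/sqrt(w) is the sampling error of one window median
        stat_sd = 1.25 * sigma_local * np.sqrt(2.0 / window)
        thresh = max(sigma_mult * stat_sd, min_jump)
        jump = float(np.median(post) - np.median(pre))
        if sign * jump <= thresh:
            continue
        # refine: localise the rip as the position maximising the jump of
        # short (8-sample) flanking medians; gates are then evaluated tight
        # around it
        best, j_star = -np.inf, None
        for k in range(max(i - window, 8), min(i + window, n - 8)):
            a = resid[k - 7 : k + 1]
            b = resid[k + 1 : k + 9]
            if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
                continue
            mj = sign * float(np.median(b) - np.median(a))
            if mj > best:
                best, j_star = mj, k
        if j_star is None:
            continue
        # the refined index can still sit a couple of samples off the rip;
        # accept the first nearby candidate that clears every gate
        hit = None
        for j in range(max(j_star - 3, 8), min(j_star + 4, n - 8)):
            hit = _check_candidate(
                resid, resid_u, F, j, n, window, thresh, sign, ev_dir, lo, hi
            )
            if hit is not None:
                break
        if hit is not None:
            return hit
    return None


def _check_candidate(resid, resid_u, F, j, n, window, thresh, sign, ev_dir, lo, hi):
    """Gate one putative rip index; return (index, jump, force) or None."""
    half_w = max(window // 2, 8)
    pre_j = resid[max(j - half_w, 0) : j + 1]
    post_j = resid[j + 1 : min(j + 1 + half_w, n)]
    if len(pre_j) < 6 or len(post_j) < 6:
        return None
    if not (np.all(np.isfinite(pre_j)) and np.all(np.isfinite(post_j))):
        return None
    jump = float(np.median(post_j) - np.median(pre_j))
    if sign * jump <= thresh:
        return None
    # a real rip relaxes the tether: across the rip the force moves
    # against the local ramp trend
    ramp1 = float(np.median(np.diff(F[lo:hi])))
    f_pre = float(np.median(F[max(j - 8, 0) : j + 1]))
    f_post = float(np.median(F[j + 1 : min(j + 10, n)]))
    # the pre-window median lags the rip by ~4 samples of ramp
    f_at = f_pre + 4.0 * ramp1
    ramp9 = ramp1 * 9.0
    if ev_dir == "unfold" and not (f_post - f_pre < ramp9 - 0.3):
        return None
    if ev_dir == "refold" and not (f_post - f_pre > ramp9 + 0.3):
        return None
    # the post-rip samples must fit the target-state model
    if resid_u is not None:
        alt_post = resid_u[j + 1 : min(j + 1 + half_w, n)]
        if ev_dir == "unfold":
            r_target = np.median(alt_post)
            r_source = np.median(post_j)
        else:
            r_target = np.median(post_j)  # folded-model residual
            r_source = np.median(alt_post)
        if not abs(r_target) < abs(r_source):
            return None
    return j, jump, f_at


def contour_length_change(
    event: TransitionEvent,
    trace: PullTrace,
    model: TetherModel,
    *,
    min_segment: int = 20,
    fit_range: tuple[float, float] = (5.0, 35.0),
) -> TransitionEvent:
    """Refine an event's contour-length change by segment fits.

    The protein contour length is fitted separately to the pre- and
    post-transition segments (all other tether parameters held fixed; fits
    restricted to ``fit_range`` pN where the eWLC describes the handles);
    their difference is the released contour, converted to residues at
    ``model.contour_per_aa``.  The fit minimises force-space residuals
    (measured force noise is homoscedastic, whereas extension residuals
    inherit the strongly force-dependent handle compliance), and the
    fit-range mask is applied to a median-smoothed force so that noise at
    the range boundaries does not select one-sided residuals.  Returns a
    new event with the refined values; raises when either segment is too
    short or a fit fails.
    """
    from scipy.ndimage import median_filter

    seg_dir = "pull" if event.direction == "unfold" else "relax"
    seg = trace.segment(event.cycle, seg_dir)
    F, x = seg["force"], seg["extension"]
    # guard gap: the detected index can sit a few samples either side of
    # the true rip, so exclude a band around it from both fits
    i = event.index
    pre_F, pre_x = F[: max(i - 4, 0)], x[: max(i - 4, 0)]
    post_F, post_x = F[i + 8 :], x[i + 8 :]
    if event.direction == "unfold":
        states = ("folded", "unfolded")
    else:
        states = ("unfolded", "folded")

    f_grid = np.linspace(0.5, 80.0, 1000)
    dna_curve = ewlc_extension(f_grid, model.P_dna, model.Lc_dna, model.S_dna, model.kbt)

    def fit_seg(Fs, xs, state):
        if len(Fs) < min_segment:
            raise ValueError(
                f"segment has {len(Fs)} samples (< {min_segment})"
            )
        f_smooth = median_filter(Fs, size=9, mode="nearest")
        m = (f_smooth >= fit_range[0]) & (f_smooth <= fit_range[1])
        if np.count_nonzero(m) < min_segment:
            raise ValueError(
                f"segment has {np.count_nonzero(m)} usable samples "
                f"(< {min_segment}) in the {fit_range} pN fit range"
            )
        Fs, xs = Fs[m], xs[m]
        off = model.folded_size if state == "folded" else 0.0

        def resid(p):
            (Lc,) = p
            x_curve = dna_curve + odijk_extension(f_grid, model.P_prot, Lc, model.kbt) + off
            return np.interp(xs, x_curve, f_grid) - Fs

        res = least_squares(resid, x0=[max(model.released_contour, 1.0)], bounds=(1e-3, 1e4))
        if not res.success:
            raise ValueError("protein contour fit did not converge")
        return float(res.x[0])

    Lc_pre = fit_seg(pre_F, pre_x, states[0])
    Lc_post = fit_seg(post_F, post_x, states[1])
    folded_corr = 0.0  # folded size is held fixed; contours compare directly
    if event.direction == "unfold":
        dnm = Lc_post - Lc_pre + folded_corr
    else:
        dnm = -(Lc_pre - Lc_post) - folded_corr
    return TransitionEvent(
        cycle=event.cycle,
        direction=event.direction,
        force=event.force,
        delta_Lc_nm=float(dnm),
        delta_Lc_aa=float(dnm / model.contour_per_aa),
        score=event.score,
        index=event.index,
    )


def force_stats(
    groups: dict[str, np.ndarray],
) -> tuple[list[ForceStats], pd.DataFrame]:
    """Mean/SEM per group plus pairwise Mann-Whitney U p-values.

    The U test is exact for small tie-free samples (both n <= 20) and uses
    the tie-corrected normal approximation otherwise.  Tests need n >= 3 per
    group; smaller groups still get summary statistics but NaN p-values.
    """
    stats = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        stats.append(ForceStats(label, float(np.mean(v)), sem, len(v)))
    labels = list(groups)
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            va = np.asarray(groups[labels[a]], dtype=float)
            vb = np.asarray(groups[labels[b]], dtype=float)
            if len(va) < 3 or len(vb) < 3:
                u_stat, p = float("nan"), float("nan")
            else:
                has_ties = len(np.unique(np.concatenate([va, vb]))) < len(va) + len(vb)
                if not has_ties and len(va) <= 20 and len(vb) <= 20:
                    res = mannwhitneyu(va, vb, alternative="two-sided", method="exact")
                else:
                    res = mannwhitneyu(
                        va, vb, alternative="two-sided", method="asymptotic",
                        use_continuity=False,
                    )
                u_stat, p = float(res.statistic), float(res.pvalue)
            rows.append({"group_a": labels[a], "group_b": labels[b], "U": u_stat, "p": p})
    return stats, pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p"])


def refolding_frequency(
    n_cycles: int, events: list[TransitionEvent], confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of pull-relax cycles showing a refold, with a binomial CI.

    Clopper-Pearson interval; the low refolding frequency without the
    structural ion (~16-18% of cycles) is the kind of quantity this reports.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    k = len({e.cycle for e in events if e.direction == "refold"})
    frac = k / n_cycles
    from scipy.stats import beta

    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n_cycles - k + 1))
    hi = 1.0 if k == n_cycles else float(beta.ppf(1 - alpha / 2, k + 1, n_cycles - k))
    return frac, (lo, hi)


def fret_efficiency(r, R0: float = 65.0):
    """FRET efficiency E = 1 / (1 + (r/R0)^6); r and R0 in the same units.

    With the Förster radius R0 = 65 Å, the ~20 Å terminus separation of the
    folded domain gives near-total donor quenching, while an extended chain
    at >= 100 Å transfers almost nothing.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or R0 <= 0:
        raise ValueError("distances must be positive")
    out = 1.0 / (1.0 + (r / R0) ** 6)
    return float(out) if out.ndim == 0 else out
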