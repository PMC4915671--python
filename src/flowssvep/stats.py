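"""Frequency-domain inference: T2Circ and complex-domain MANOVA.

Two complementary tests operate on the subject-level complex components
(re, im) at one harmonic:

* **T2Circ** asks whether a channel responds *at all*: it tests that the
  mean of complex responses z_1..z_n is zero, assuming circular (isotropic)
  bivariate normal noise.  With z-bar the vector mean and
  SS = sum |z_j - z-bar|^2,

      T2Circ = n (n - 1) |z-bar|^2 / SS  ~  F(2, 2n - 2)  under H0.

  It is invariant to global phase rotation and scaling of the data.

* **Pillai-trace MANOVA** asks whether a channel responds *differently*
  across conditions, jointly in amplitude and phase: the bivariate
  (cosine, sine) outcome is modelled with subject as a categorical blocking
  factor (equivalent to a random intercept in this balanced within-subject
  design) plus pattern (2 df), speed (2 df) and their interaction (4 df).
  Per effect, H and E are the hypothesis and error cross-product matrices,
  V = trace(H (H + E)^-1), and significance uses the standard Pillai-
  Bartlett F approximation.  Effect size is partial eta^2 = V / s with
  s = min(2, effect df).

The mass-univariate regime fits the identical model independently at every
channel and controls false positives only through a conservative per-test
alpha (default .0005, i.e. a Bonferroni-style 0.05/100); thresholds are
applied with strict '<'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "T2CircResult",
    "ManovaEffectResult",
    "SignificanceMapResult",
    "t2circ",
    "t2circ_map",
    "pillai_manova",
    "mass_univariate",
    "omnibus_manova",
    "partial_eta_sq",
    "DEFAULT_ALPHA",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_ALPHA = 0.0005
DEFAULT_THRESHOLDS = (0.05, 0.01, 0.005, 0.001, 0.0005)


@dataclass(frozen=True)
class T2CircResult:
    """Zero-mean test of complex responses for one channel/condition."""

    statistic: float
    df1: int
    df2: int
    p: float
    n: int
    channel: int | None = None
    harmonic: str | None = None
    pattern: str | None = None
    speed: float | None = None


@dataclass(frozen=True)
class ManovaEffectResult:
    """One effect of the bivariate (re, im) linear model at one channel."""

    effect: str
    pillai: float
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    n: int | None = None
    channel: int | None = None
    harmonic: str | None = None


@dataclass(frozen=True)
class SignificanceMapResult:
    """Channel-wise MANOVA table plus per-threshold significant-channel sets."""

    table: pd.DataFrame
    alpha: float
    thresholds: tuple
    significant: dict = field(default_factory=dict)

    def significant_channels(self, effect: str, alpha: float | None = None):
        alpha = self.alpha if alpha is None else alpha
        return self.significant[(effect, alpha)]


def partial_eta_sq(V: float, s: int) -> float:
    """Effect size for a Pillai trace V with s = min(p, q): V / s in [0, 1]."""
    if s < 1:
        raise ValueError("s must be >= 1")
    if V < -1e-12 or V > s + 1e-12:
        raise ValueError(f"Pillai trace {V} outside [0, {s}]")
    return float(np.clip(V / s, 0.0, 1.0))


# ---------------------------------------------------------------------------
# T2Circ
# ---------------------------------------------------------------------------

def _t2circ_arrays(z: np.ndarray, axis: int = -1):
    """Vectorized T2Circ statistic and p along ``axis``; returns (stat, p, n)."""
    z = np.asarray(z, dtype=complex)
    n = z.shape[axis]
    if n < 2:
        raise ValueError("T2Circ requires at least two observations")
    zbar = z.mean(axis=axis, keepdims=True)
    ss = np.sum(np.abs(z - zbar) ** 2, axis=axis)
    zbar = np.squeeze(zbar, axis=axis)
    num = n * (n - 1) * np.abs(zbar) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(ss > 0, num / np.where(ss > 0, ss, 1.0), np.inf)
    p = sstats.f.sf(stat, 2, 2 * n - 2)
    degenerate = ss == 0
    if np.any(degenerate):
        # SS = 0 with nonzero mean: perfect coherence, p -> 0 (warn);
        # SS = 0 with zero mean: all-zero data, p = 1
        zero_mean = np.abs(zbar) == 0
        stat = np.where(degenerate & zero_mean, 0.0, stat)
        p = np.where(degenerate & zero_mean, 1.0, p)
        p = np.where(degenerate & ~zero_mean, 0.0, p)
        if np.any(degenerate & ~zero_mean):
            warnings.warn(
                "T2Circ: zero within-sample scatter with nonzero mean; "
                "p reported as 0",
                RuntimeWarning,
                stacklevel=3,
            )
    return stat, p, n


def t2circ(z, channel=None, harmonic=None, pattern=None, speed=None) -> T2CircResult:
    """T2Circ test that the mean of complex responses is zero."""
    z = np.asarray(z, dtype=complex).ravel()
    stat, p, n = _t2circ_arrays(z)
    return T2CircResult(
        statistic=float(stat),
        df1=2,
        df2=2 * n - 2,
        p=float(p),
        n=n,
        channel=channel,
        harmonic=harmonic,
        pattern=pattern,
        speed=speed,
    )


def t2circ_map(
    components: pd.DataFrame,
    harmonic: str,
    by_condition: bool = True,
) -> pd.DataFrame:
    """Channel-wise T2Circ table at one harmonic.

    ``by_condition=True`` tests each (pattern, speed) cell with subjects as
    observations (the 3 x 3 grid of condition maps); ``False`` pools every
    subject x pattern x speed component as an observation (the overall
    responsiveness map).  Output columns: channel [, pattern, speed],
    statistic, df1, df2, p, n.
    """
    d = components[components.harmonic == harmonic]
    if d.empty:
        raise ValueError(f"no components at harmonic {harmonic!r}")
    rows = []
    if by_condition:
        groups = d.groupby(["channel", "pattern", "speed"], sort=True)
    else:
        groups = d.groupby(["channel"], sort=True)
    for key, g in groups:
        z = (g.re + 1j * g.im).to_numpy()
        stat, p, n = _t2circ_arrays(z)
        row = {"channel": key[0] if by_condition else key[0]}
        if by_condition:
            row["pattern"], row["speed"] = key[1], key[2]
        row.update(
            statistic=float(stat), df1=2, df2=2 * n - 2, p=float(p), n=n
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pillai MANOVA machinery
# ---------------------------------------------------------------------------

def _sum_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Deviation (sum-to-zero) coding: L levels -> L-1 columns."""
    levels = sorted(pd.unique(labels).tolist())
    L = len(levels)
    X = np.zeros((labels.shape[0], L - 1))
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
    X[labels == levels[-1], :] = -1.0
    return X, levels


def _interaction(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise products of two coded factors."""
    n = A.shape[0]
    return (A[:, :, None] * B[:, None, :]).reshape(n, -1)


def _pillai_f(V: float, p: int, q: int, dfe: int):
    """Standard Pillai-Bartlett F approximation.

    p = number of outcomes, q = effect df, dfe = error df.
    """
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (dfe - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0:
        raise ValueError("error df too small for the Pillai F approximation")
    denom = s - V
    F = (df2 / df1) * (V / denom) if denom > 1e-12 else np.inf
    pval = float(sstats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return s, F, df1, df2, pval


def _sequential_blocks(X_blocks: list[np.ndarray]) -> tuple[np.ndarray, list]:
    """QR of the concatenated design; returns Q and per-block column ranges.

    With a balanced within-subject design and sum-to-zero coding the blocks
    span mutually orthogonal subspaces, so the sequential (Type I) cross
    products computed from Q coincide with Type III.
    """
    X = np.concatenate(X_blocks, axis=1)
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-9 * max(1.0, diag.max())):
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    ranges, start = [], 0
    for b in X_blocks:
        ranges.append((start, start + b.shape[1]))
        start += b.shape[1]
    return Q, ranges


def _manova_from_projection(
    Y: np.ndarray, Q: np.ndarray, ranges: list, names: list[str],
    effect_slots: dict[str, int],
) -> dict[str, tuple[np.ndarray, int]]:
    """Per-effect H matrices and the error matrix E for stacked outcomes.

    ``Y`` is (..., N, p).  Returns {"_E": (E, dfe), effect: (H, q), ...}.
    """
    T = np.einsum("nk,...np->...kp", Q, Y)       # (..., K, p)
    E = np.einsum("...np,...nq->...pq", Y, Y) - np.einsum(
        "...kp,...kq->...pq", T, T
    )
    N = Y.shape[-2]
    K = Q.shape[1]
    out = {"_E": (E, N - K)}
    for name, slot in effect_slots.items():
        a, b = ranges[slot]
        Tb = T[..., a:b, :]
        H = np.einsum("...kp,...kq->...pq", Tb, Tb)
        out[name] = (H, b - a)
    return out


def _pillai_from_HE(H: np.ndarray, E: np.ndarray, q: int, dfe: int,
                    p: int = 2):
    """Pillai V, F, dfs, p-value and partial eta^2 from one H/E pair."""
    try:
        M = np.linalg.solve((H + E).T, H.T).T  # (H+E)^-1 applied to H
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular H+E matrix (degenerate channel data)"
        ) from err
    V = float(np.clip(np.trace(M), 0.0, min(p, q)))
    s, F, df1, df2, pval = _pillai_f(V, p, q, dfe)
    return V, s, F, df1, df2, pval


def _within_subject_design(d: pd.DataFrame):
    """Blocks for the subject-blocked pattern x speed model.

    Requires a complete balanced layout: every subject has every
    pattern x speed cell exactly once.
    """
    counts = d.groupby(["subject", "pattern", "speed"]).size()
    n_cells = d.pattern.nunique() * d.speed.nunique()
    if (counts != 1).any() or len(counts) != d.subject.nunique() * n_cells:
        raise ValueError(
            "unbalanced design: every subject needs exactly one component "
            "per pattern x speed cell"
        )
    n_subj = d.subject.nunique()
    if n_subj < 3:
        raise ValueError("need at least three subjects")
    S, _ = _sum_code(d.subject.to_numpy())
    P, _ = _sum_code(d.pattern.to_numpy())
    V, _ = _sum_code(d.speed.to_numpy())
    blocks = [
        np.ones((len(d), 1)),
        S,
        P,
        V,
        _interaction(P, V),
    ]
    names = ["intercept", "subject", "pattern", "speed", "pattern:speed"]
    return blocks, names, n_subj


_EFFECTS = ("pattern", "speed", "pattern:speed")


def pillai_manova(
    channel_components: pd.DataFrame,
    channel: int | None = None,
    harmonic: str | None = None,
) -> list[ManovaEffectResult]:
    """Subject-blocked bivariate MANOVA for one channel.

    ``channel_components`` needs columns subject, pattern, speed, re, im
    (one row per subject x condition).  Returns pattern, speed and
    pattern:speed effects with Pillai V, the F approximation and partial
    eta^2 = V / s.
    """
    d = channel_components
    blocks, names, n_subj = _within_subject_design(d)
    Y = d[["re", "im"]].to_numpy(dtype=float)
    try:
        Q, ranges = _sequential_blocks(blocks)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"rank-deficient design at channel {channel}"
        ) from err
    slots = {e: names.index(e) for e in _EFFECTS}
    he = _manova_from_projection(Y, Q, ranges, names, slots)
    E, dfe = he["_E"]
    results = []
    for effect in _EFFECTS:
        H, q = he[effect]
        try:
            V, s, F, df1, df2, pval = _pillai_from_HE(H, E, q, dfe)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular error matrix at channel {channel}"
            ) from err
        results.append(
            ManovaEffectResult(
                effect=effect, pillai=V, F=F, df1=df1, df2=df2, p=pval,
                partial_eta_sq=partial_eta_sq(V, s), n=n_subj,
                channel=channel, harmonic=harmonic,
            )
        )
    return results


def mass_univariate(
    components: pd.DataFrame,
    harmonic: str,
    alpha: float = DEFAULT_ALPHA,
    thresholds: tuple = DEFAULT_THRESHOLDS,
) -> SignificanceMapResult:
    """Fit the identical MANOVA independently at every channel.

    Subjects with missing cells are removed channel-wise (listwise deletion
    at the subject level, counts reported); channels left with fewer than
    three complete subjects are reported as NA rather than dropped.  No
    multiplicity correction is applied beyond the conservative per-test
    alpha; significant sets nest monotonically across thresholds.
    """
    d = components[components.harmonic == harmonic]
    if d.empty:
        raise ValueError(f"no components at harmonic {harmonic!r}")
    thresholds = tuple(sorted(set(thresholds) | {alpha}, reverse=True))
    channels = np.sort(d.channel.unique())

    # channels sharing the same complete-subject set are fit in one batch
    rows = []
    n_cells = d.pattern.nunique() * d.speed.nunique()
    ok = d[np.isfinite(d.re) & np.isfinite(d.im)]
    cnt = ok.groupby(["channel", "subject"]).size()
    complete_by_channel = {ch: () for ch in channels}
    full = cnt[cnt == n_cells].reset_index()
    for ch, g in full.groupby("channel"):
        complete_by_channel[ch] = tuple(sorted(g.subject))

    groups: dict[tuple, list] = {}
    for ch, subs in complete_by_channel.items():
        groups.setdefault(subs, []).append(ch)

    for subs, chans in groups.items():
        if len(subs) < 3:
            for ch in chans:
                for effect in _EFFECTS:
                    rows.append(
                        dict(channel=ch, effect=effect, pillai=np.nan,
                             F=np.nan, df1=np.nan, df2=np.nan, p=np.nan,
                             partial_eta_sq=np.nan, n=len(subs))
                    )
            continue
        sel = d[d.channel.isin(chans) & d.subject.isin(subs)]
        # common observation order across channels
        one = sel[sel.channel == chans[0]].sort_values(
            ["subject", "pattern", "speed"], kind="mergesort"
        )
        blocks, names, n_subj = _within_subject_design(one)
        Q, ranges = _sequential_blocks(blocks)
        slots = {e: names.index(e) for e in _EFFECTS}
        wide = sel.sort_values(
            ["channel", "subject", "pattern", "speed"], kind="mergesort"
        )
        N = len(one)
        Y = wide[["re", "im"]].to_numpy(dtype=float).reshape(len(chans), N, 2)
        he = _manova_from_projection(Y, Q, ranges, names, slots)
        E, dfe = he["_E"]
        for effect in _EFFECTS:
            Hs, q = he[effect]
            for ci, ch in enumerate(sorted(chans)):
                V, s, F, df1, df2, pval = _pillai_from_HE(
                    Hs[ci], E[ci], q, dfe
                )
                rows.append(
                    dict(channel=ch, effect=effect, pillai=V, F=F, df1=df1,
                         df2=df2, p=pval,
                         partial_eta_sq=partial_eta_sq(V, s), n=n_subj)
                )
    table = (
        pd.DataFrame(rows)
        .sort_values(["effect", "channel"], kind="mergesort")
        .reset_index(drop=True)
    )
    significant = {}
    for effect in _EFFECTS:
        te = table[table.effect == effect]
        for thr in thresholds:
            sig = te.channel[te.p < thr].to_numpy()
            significant[(effect, thr)] = np.sort(sig)
    return SignificanceMapResult(
        table=table, alpha=alpha, thresholds=thresholds,
        significant=significant,
    )


# ---------------------------------------------------------------------------
# Omnibus pooled model
# ---------------------------------------------------------------------------

def omnibus_manova(
    components: pd.DataFrame,
    harmonic: str,
    ages: dict | pd.Series,
) -> list[ManovaEffectResult]:
    """Single pooled model over all channels at one harmonic.

    Observations are subject x channel x condition components; predictors
    are participant age (in weeks, centered), channel, pattern, speed, and
    the channel x pattern and channel x speed interactions, entered in that
    order.  The error stratum is the pooled residual; dfs follow this
    model's own bookkeeping.  A constant age vector drops the age term with
    a warning; a single channel drops the channel terms with a warning.
    """
    d = components[components.harmonic == harmonic].copy()
    if d.empty:
        raise ValueError(f"no components at harmonic {harmonic!r}")
    ages = pd.Series(dict(ages)) if not isinstance(ages, pd.Series) else ages
    missing = set(d.subject.unique()) - set(ages.index)
    if missing:
        raise ValueError(f"ages missing for subjects: {sorted(missing)}")
    d = d.sort_values(
        ["subject", "channel", "pattern", "speed"], kind="mergesort"
    )
    N = len(d)
    age = ages.loc[d.subject].to_numpy(dtype=float)

    blocks = [np.ones((N, 1))]
    names = ["intercept"]
    if np.ptp(age) == 0:
        warnings.warn(
            "age is constant; dropping the age term", UserWarning, stacklevel=2
        )
    else:
        blocks.append((age - age.mean())[:, None])
        names.append("age")
    n_channels = d.channel.nunique()
    P, _ = _sum_code(d.pattern.to_numpy())
    V, _ = _sum_code(d.speed.to_numpy())
    if n_channels < 2:
        warnings.warn(
            "only one channel; dropping channel terms", UserWarning,
            stacklevel=2,
        )
        blocks += [P, V]
        names += ["pattern", "speed"]
    else:
        C, _ = _sum_code(d.channel.to_numpy())
        blocks += [C, P, V, _interaction(C, P), _interaction(C, V)]
        names += ["channel", "pattern", "speed", "channel:pattern",
                  "channel:speed"]
    Y = d[["re", "im"]].to_numpy(dtype=float)
    Q, ranges = _sequential_blocks(blocks)
    effects = [n for n in names if n != "intercept"]
    slots = {e: names.index(e) for e in effects}
    he = _manova_from_projection(Y, Q, ranges, names, slots)
    E, dfe = he["_E"]
    results = []
    for effect in effects:
        H, q = he[effect]
        Vp, s, F, df1, df2, pval = _pillai_from_HE(H, E, q, dfe)
        results.append(
            ManovaEffectResult(
                effect=effect, pillai=Vp, F=F, df1=df1, df2=df2, p=pval,
                partial_eta_sq=partial_eta_sq(Vp, s),
                n=d.subject.nunique(), harmonic=harmonic,
            )
        )
    return results
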