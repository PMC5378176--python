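"""GC-biased gene conversion signatures: substitution polarization,
binned weak<->strong counts and equilibrium GC (GC*) profiles.

Recombination repair intermediates are resolved with a bias favouring G/C
(strong, S) over A/T (weak, W) alleles, so historical recombination
elevates the W->S substitution rate. The equilibrium GC content is

    GC* = r_WS / (r_WS + r_SW),   r_WS = n_WS / N_W,  r_SW = n_SW / N_S,

where ``n`` are lineage-specific substitution counts and ``N`` the
ancestral W/S site opportunities, aggregated over all peak centers in
10-bp offset bins. Substitutions are polarized onto the two focal mouse
lineages (M. m. domesticus, M. m. castaneus) by parsimony against the
M. spretus outgroup: a site where the two focal lineages disagree and the
outgroup matches one of them is a single substitution on the other branch.

The opportunity-normalized estimator is the default because the raw count
ratio n_WS / (n_WS + n_SW) is confounded by base composition; the raw
variant is available via ``raw_ratio=True`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .classify import StatTestResult
from .motifs import encode

WEAK_CODES = (0, 3)  # A, T
STRONG_CODES = (1, 2)  # C, G
LINEAGES = ("domesticus", "castaneus")

__all__ = [
    "LINEAGES", "PolarizationResult", "GCStarProfile",
    "polarize_substitutions", "bin_substitutions",
    "estimate_gc_star", "gc_star_standard_error", "add_gc_star",
    "fit_smoothing_spline", "compare_lineages",
]


class DataConsistencyError(ValueError):
    """Raised when substitution counts exceed their opportunity tallies."""


@dataclass
class PolarizationResult:
    """Polarized substitution calls plus per-site ancestral tallies.

    ``calls`` has columns chrom, pos, lineage, ancestral, derived, category
    (WS/SW/WW/SS); ``tallies`` has columns chrom, pos, weak (bool) -- one
    row per polarizable site, contributing to both lineages' opportunity
    counts. Unpolarizable sites (outgroup matching neither focal base, or
    any N) are discarded from both.
    """

    calls: pd.DataFrame
    tallies: pd.DataFrame


def _coerce_base_column(col: pd.Series) -> np.ndarray:
    vals = col.to_numpy()
    if np.issubdtype(vals.dtype, np.integer):
        codes = vals.astype(np.uint8)
    else:
        codes = encode("".join(str(v).upper() for v in vals))
    if codes.max(initial=0) > 4:
        raise ValueError("invalid base character in alignment table")
    return codes


_CATEGORY = np.empty((5, 5), dtype="U2")
for _a in range(4):
    for _d in range(4):
        aw = _a in WEAK_CODES
        dw = _d in WEAK_CODES
        _CATEGORY[_a, _d] = ("W" if aw else "S") + ("W" if dw else "S")

_LETTER = np.array(list("ACGTN"))


def _letters(codes: np.ndarray) -> np.ndarray:
    return _LETTER[codes]


def polarize_substitutions(
    triples: pd.DataFrame,
    exclude_cpg: bool = False,
) -> PolarizationResult:
    """Assign substitutions to the focal branches by outgroup parsimony.

    ``triples`` must be sorted by (chrom, pos) with base columns
    ``base_lineage1`` (domesticus), ``base_lineage2`` (castaneus) and
    ``base_outgroup`` as letters or uint8 codes. With ``exclude_cpg``,
    calls whose ancestral base forms a CpG dinucleotide with the ancestral
    base of an adjacent tabulated position are dropped (CpG
    hypermutability can mimic S->W flux).
    """
    chrom = triples["chrom"].to_numpy()
    pos = triples["pos"].to_numpy()
    order_ok = np.all(
        (chrom[:-1] < chrom[1:])
        | ((chrom[:-1] == chrom[1:]) & (pos[:-1] < pos[1:]))
    ) if len(triples) > 1 else True
    if not order_ok:
        raise ValueError("alignment table must be sorted by (chrom, pos)")

    b1 = _coerce_base_column(triples["base_lineage1"])
    b2 = _coerce_base_column(triples["base_lineage2"])
    bo = _coerce_base_column(triples["base_outgroup"])
    valid = (b1 < 4) & (b2 < 4) & (bo < 4)

    all_equal = valid & (b1 == b2) & (b1 == bo)
    # focal disagreement where the outgroup resolves the ancestral state
    dom_call = valid & (b1 != b2) & (b2 == bo)  # change on domesticus branch
    cast_call = valid & (b1 != b2) & (b1 == bo)  # change on castaneus branch
    usable = all_equal | dom_call | cast_call

    tallies = pd.DataFrame(
        {
            "chrom": chrom[usable],
            "pos": pos[usable],
            "weak": np.isin(bo[usable], WEAK_CODES),
        }
    )

    frames = []
    for lineage, mask, derived in (
        ("domesticus", dom_call, b1),
        ("castaneus", cast_call, b2),
    ):
        anc = bo[mask]
        der = derived[mask]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom[mask],
                    "pos": pos[mask],
                    "lineage": lineage,
                    "ancestral": _letters(anc),
                    "derived": _letters(der),
                    "category": _CATEGORY[anc, der],
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)

    if exclude_cpg and len(calls):
        anc_codes = bo.copy()
        # ancestral CpG context among tabulated neighbours (same chrom, pos +- 1)
        nxt_c = np.zeros(len(triples), bool)
        prv_g = np.zeros(len(triples), bool)
        adjacent_next = np.zeros(len(triples), bool)
        adjacent_prev = np.zeros(len(triples), bool)
        if len(triples) > 1:
            adjacent_next[:-1] = (chrom[:-1] == chrom[1:]) & (pos[1:] - pos[:-1] == 1)
            adjacent_prev[1:] = adjacent_next[:-1]
        nxt_c[:-1] = adjacent_next[:-1] & (anc_codes[:-1] == 1) & (anc_codes[1:] == 2)
        prv_g[1:] = adjacent_prev[1:] & (anc_codes[1:] == 2) & (anc_codes[:-1] == 1)
        cpg_flag = nxt_c | prv_g
        flagged = pd.DataFrame({"chrom": chrom, "pos": pos, "cpg": cpg_flag})
        calls = calls.merge(flagged, on=["chrom", "pos"], how="left")
        calls = calls[~calls["cpg"].fillna(False)].drop(columns="cpg")
        calls = calls.reset_index(drop=True)

    calls = calls.sort_values(["chrom", "pos", "lineage"], ignore_index=True)
    return PolarizationResult(calls=calls, tallies=tallies)


def _per_center_histogram(
    positions: np.ndarray,
    weights_masks: Sequence[np.ndarray],
    centers: np.ndarray,
    bin_width: int,
    n_bins: int,
    extent: int,
    accumulators: Sequence[np.ndarray],
) -> None:
    """Accumulate per-bin counts of (sorted) positions around each center.

    A position in the windows of two centers is counted once per center.
    """
    for c in centers:
        lo = np.searchsorted(positions, c - extent, side="left")
        hi = np.searchsorted(positions, c + extent, side="left")
        if hi <= lo:
            continue
        bins = (positions[lo:hi] - c + extent) // bin_width
        for mask, acc in zip(weights_masks, accumulators):
            acc += np.bincount(bins, weights=mask[lo:hi], minlength=n_bins)


def bin_substitutions(
    calls: pd.DataFrame,
    tallies: pd.DataFrame,
    centers: Sequence[tuple[str, int]],
    bin_width: int = 10,
    extent: int = 2000,
) -> dict[str, pd.DataFrame]:
    """Aggregate substitutions and opportunities in offset bins per lineage.

    Offsets d = pos - center with d in [-extent, extent) are assigned to
    bin floor(d / bin_width); the returned tables have one row per bin with
    columns offset (bin start), n_WS, n_SW, N_W, N_S.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not len(centers):
        raise ValueError("centers must be non-empty")
    n_bins = (2 * extent) // bin_width
    offsets = np.arange(n_bins) * bin_width - extent

    centers_by_chrom: dict[str, list[int]] = {}
    for chrom, c in centers:
        centers_by_chrom.setdefault(chrom, []).append(c)

    out: dict[str, pd.DataFrame] = {}
    tal_sorted = tallies.sort_values(["chrom", "pos"])
    for lineage in LINEAGES:
        sub = calls[calls["lineage"] == lineage].sort_values(["chrom", "pos"])
        n_ws = np.zeros(n_bins)
        n_sw = np.zeros(n_bins)
        n_w = np.zeros(n_bins)
        n_s = np.zeros(n_bins)
        for chrom, cs in centers_by_chrom.items():
            c_arr = np.sort(np.asarray(cs))
            s = sub[sub["chrom"] == chrom]
            pos = s["pos"].to_numpy()
            is_ws = (s["category"] == "WS").to_numpy(dtype=float)
            is_sw = (s["category"] == "SW").to_numpy(dtype=float)
            _per_center_histogram(
                pos, [is_ws, is_sw], c_arr, bin_width, n_bins, extent, [n_ws, n_sw]
            )
            t = tal_sorted[tal_sorted["chrom"] == chrom]
            tpos = t["pos"].to_numpy()
            weak = t["weak"].to_numpy(dtype=float)
            _per_center_histogram(
                tpos, [weak, 1.0 - weak], c_arr, bin_width, n_bins, extent, [n_w, n_s]
            )
        out[lineage] = pd.DataFrame(
            {
                "offset": offsets,
                "n_WS": n_ws.astype(int),
                "n_SW": n_sw.astype(int),
                "N_W": n_w.astype(int),
                "N_S": n_s.astype(int),
            }
        )
    return out


def estimate_gc_star(
    n_ws: float, n_w: float, n_sw: float, n_s: float, raw_ratio: bool = False
) -> float:
    """Equilibrium GC from binned counts; NaN when no informative events.

    Default: opportunity-normalized rates r_WS = n_WS/N_W, r_SW = n_SW/N_S,
    GC* = r_WS / (r_WS + r_SW). ``raw_ratio`` uses n_WS / (n_WS + n_SW).
    """
    if n_ws + n_sw == 0:
        return float("nan")
    if raw_ratio:
        return n_ws / (n_ws + n_sw)
    if (n_w == 0 and n_ws > 0) or (n_s == 0 and n_sw > 0):
        raise DataConsistencyError(
            "substitution counts without ancestral opportunities"
        )
    r_ws = n_ws / n_w if n_w > 0 else 0.0
    r_sw = n_sw / n_s if n_s > 0 else 0.0
    return r_ws / (r_ws + r_sw)


def gc_star_standard_error(n_ws: float, n_w: float, n_sw: float, n_s: float) -> float:
    """Delta-method SE of GC* from the two binomial substitution counts."""
    if min(n_w, n_s) <= 0 or n_ws + n_sw == 0:
        return float("nan")
    r_ws = n_ws / n_w
    r_sw = n_sw / n_s
    denom = (r_ws + r_sw) ** 2
    if denom == 0:
        return float("nan")
    var_ws = r_ws * (1 - r_ws) / n_w
    var_sw = r_sw * (1 - r_sw) / n_s
    # d(GC*)/dr_WS = r_SW / denom ; d(GC*)/dr_SW = -r_WS / denom
    return float(np.sqrt((r_sw / denom) ** 2 * var_ws + (r_ws / denom) ** 2 * var_sw))


def add_gc_star(bins: pd.DataFrame, raw_ratio: bool = False) -> pd.DataFrame:
    """Append gc_star and its standard error to a binned count table."""
    out = bins.copy()
    out["gc_star"] = [
        estimate_gc_star(r.n_WS, r.N_W, r.n_SW, r.N_S, raw_ratio=raw_ratio)
        for r in bins.itertuples()
    ]
    out["gc_star_se"] = [
        gc_star_standard_error(r.n_WS, r.N_W, r.n_SW, r.N_S)
        for r in bins.itertuples()
    ]
    return out


@dataclass
class GCStarProfile:
    """Binned GC* values for one lineage around a set of site centers."""

    lineage: str
    bins: pd.DataFrame  # offset, n_WS, n_SW, N_W, N_S, gc_star[, spline]
    bin_width: int = 10

    @property
    def midpoints(self) -> np.ndarray:
        return self.bins["offset"].to_numpy() + self.bin_width / 2.0


def build_profiles(
    calls: pd.DataFrame,
    tallies: pd.DataFrame,
    centers: Sequence[tuple[str, int]],
    bin_width: int = 10,
    extent: int = 2000,
    raw_ratio: bool = False,
    spline: bool = True,
) -> dict[str, GCStarProfile]:
    """Convenience wrapper: bin, estimate GC* and (optionally) smooth."""
    binned = bin_substitutions(calls, tallies, centers, bin_width, extent)
    profiles = {}
    for lineage, table in binned.items():
        table = add_gc_star(table, raw_ratio=raw_ratio)
        prof = GCStarProfile(lineage=lineage, bins=table, bin_width=bin_width)
        if spline and table["gc_star"].notna().sum() >= 4:
            fit_smoothing_spline(prof)
        profiles[lineage] = prof
    return profiles


def fit_smoothing_spline(
    profile: GCStarProfile, lam: float | None = None
) -> np.ndarray:
    """Cubic smoothing spline through the defined bins of a profile.

    Smoothing is chosen by generalized cross-validation when ``lam`` is
    None; ``lam=0`` interpolates. Fitted values are written to a
    ``spline`` column (NaN on undefined bins) and returned for the defined
    bins in offset order.
    """
    table = profile.bins
    defined = table["gc_star"].notna().to_numpy()
    if defined.sum() < 4:
        raise ValueError("need >= 4 defined bins to fit a smoothing spline")
    x = profile.midpoints[defined]
    y = table.loc[defined, "gc_star"].to_numpy()
    spl = make_smoothing_spline(x, y, lam=lam)
    fitted = spl(x)
    col = np.full(len(table), np.nan)
    col[defined] = fitted
    profile.bins = table.assign(spline=col)
    return fitted


def compare_lineages(
    profile_dom: GCStarProfile,
    profile_cast: GCStarProfile,
    center_window: int = 500,
    equal_var: bool = False,
) -> StatTestResult:
    """Two-sample t-test on per-bin GC* between lineages near the center.

    Bins whose midpoint lies within +-``center_window`` bp of the site
    center and with defined GC* enter the test; Welch's unequal-variance
    form is the default.
    """
    vals = []
    for prof in (profile_dom, profile_cast):
        mids = prof.midpoints
        sel = (np.abs(mids) <= center_window) & prof.bins["gc_star"].notna().to_numpy()
        vals.append(prof.bins.loc[sel, "gc_star"].to_numpy())
    a, b = vals
    if len(a) < 2 or len(b) < 2:
        raise ValueError("fewer than 2 defined bins in the center window")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: constant profiles; identical means -> no difference
        if a[0] == b[0]:
            return StatTestResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return StatTestResult(float("inf"), float(len(a) + len(b) - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return StatTestResult(float(res.statistic), float(res.df), float(res.pvalue))
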