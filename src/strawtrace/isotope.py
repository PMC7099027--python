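"""Two end-member ¹³C mixing and soil organic carbon mass-balance bookkeeping.

A soil amended with isotopically enriched straw carries a ¹³C signature that
is a mixture of two end members: the unamended soil (δ¹³C_s, near natural
abundance) and the straw (δ¹³C_m, strongly enriched).  Converting measured
(C content, δ¹³C) pairs per pool into straw-derived C masses uses three
steps: δ → isotope ratio against the PDB standard, ratio → ¹³C atom
fraction, and atom fraction × C content → ¹³C mass.  The straw contribution
to a pool (F_m) follows from linear interpolation between the end members in
δ space; the fraction of the added straw C residing in a pool
(the allocation fraction) follows from excess-¹³C mass balance against a
matched control.

All δ values are in ‰ relative to PDB; C contents are mg C per kg dry soil
unless noted.  Functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ¹³C/¹²C ratio of the PDB (Pee Dee Belemnite) standard.
R_PDB = 0.0112372

#: δ¹³C below which the implied isotope ratio would be non-positive.
DELTA_MIN = -1000.0

#: The four measured SOC fractions whose allocation fractions sum to the
#: per-day total straw-C conversion.
FRACTION_POOLS = ("DOC", "MBC", "POC", "MaOC")

#: All pool labels the long-format table may carry.
KNOWN_POOLS = FRACTION_POOLS + ("SOC",)

#: Required columns of the long-format pool measurement table.
POOL_TABLE_COLUMNS = (
    "treatment",
    "replicate",
    "day",
    "pool",
    "c_content_mg_per_kg",
    "delta13c_permil",
)


class IsotopeError(ValueError):
    """Base class for isotope mass-balance errors."""


class InvalidDeltaError(IsotopeError):
    """δ¹³C at or below −1000‰ (the isotope ratio would be ≤ 0)."""


class InvalidRatioError(IsotopeError):
    """Non-positive isotope ratio."""


class DegenerateMixingError(IsotopeError):
    """End members coincide; the mixing model cannot attribute sources."""


class NegativeFlushError(IsotopeError):
    """Fumigated extract carries less C than the non-fumigated one."""


class InfeasibleMassBalanceError(IsotopeError):
    """A remainder pool would need negative mass or negative ¹³C."""


class PairingError(IsotopeError):
    """No matched control record for an amended measurement."""


class IncompleteDesignError(IsotopeError):
    """Measurement table is missing design cells; lists the missing keys."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        preview = ", ".join(map(str, self.missing[:8]))
        more = "" if len(self.missing) <= 8 else f" (+{len(self.missing) - 8} more)"
        super().__init__(
            f"incomplete design: {len(self.missing)} missing "
            f"(treatment, replicate, day, pool) cells: {preview}{more}"
        )


class MixingRangeWarning(UserWarning):
    """A contribution or allocation fell outside [0, 100]%."""


@dataclass(frozen=True)
class IsotopeEndMembers:
    """δ¹³C end members of the two-source mixing model.

    Parameters
    ----------
    delta_soil : float
        δ¹³C of the unamended (control) soil, ‰.
    delta_straw : float
        δ¹³C of the labelled straw, ‰.
    r_standard : float
        ¹³C/¹²C ratio of the PDB standard (fixed physical constant).
    """

    delta_soil: float
    delta_straw: float
    r_standard: float = R_PDB

    def __post_init__(self):
        for name in ("delta_soil", "delta_straw"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= DELTA_MIN:
                raise InvalidDeltaError(f"{name}={v!r} must be finite and > {DELTA_MIN}‰")
        if self.delta_straw == self.delta_soil:
            raise DegenerateMixingError(
                "delta_straw equals delta_soil; mixing model is degenerate"
            )
        if not self.r_standard > 0:
            raise InvalidRatioError("r_standard must be positive")


@dataclass(frozen=True)
class StrawAmendment:
    """Straw added to the soil.

    straw_per_soil is g straw per kg dry soil, c_content g C per kg straw,
    total_n g N per kg straw, delta the straw δ¹³C in ‰.
    """

    straw_per_soil: float
    c_content: float
    total_n: float
    delta: float

    def __post_init__(self):
        if not self.straw_per_soil > 0:
            raise ValueError("straw_per_soil must be > 0")
        if not 0 < self.c_content < 1000:
            raise ValueError("c_content must lie in (0, 1000) g C per kg straw")
        if not np.isfinite(self.delta) or self.delta <= DELTA_MIN:
            raise InvalidDeltaError(f"straw delta={self.delta!r} out of range")

    @property
    def c_added_mg_per_kg(self) -> float:
        """Straw C added, mg C per kg soil."""
        return self.straw_per_soil * self.c_content

    @property
    def cn_ratio(self) -> float:
        """C/N mass ratio of the straw."""
        return self.c_content / self.total_n


def _maybe_scalar(x):
    arr = np.asarray(x, dtype=float)
    return float(arr) if arr.ndim == 0 else arr


def delta_to_ratio(delta, r_standard: float = R_PDB):
    """¹³C/¹²C ratio from δ¹³C (‰): R = R_std · (1 + δ/1000)."""
    d = np.asarray(delta, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= DELTA_MIN):
        raise InvalidDeltaError(f"delta must be finite and > {DELTA_MIN}‰, got {delta!r}")
    return _maybe_scalar(r_standard * (1.0 + d / 1000.0))


def ratio_to_delta(ratio, r_standard: float = R_PDB):
    """Inverse of :func:`delta_to_ratio`."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0):
        raise InvalidRatioError(f"ratio must be positive, got {ratio!r}")
    return _maybe_scalar((r / r_standard - 1.0) * 1000.0)


def ratio_to_atom_fraction(ratio):
    """Atom fraction of ¹³C in total C from the ¹³C/¹²C ratio: r/(1+r)."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0):
        raise InvalidRatioError(f"ratio must be positive, got {ratio!r}")
    return _maybe_scalar(r / (1.0 + r))


def atom_fraction_to_ratio(fraction):
    """Inverse of :func:`ratio_to_atom_fraction`: f/(1−f)."""
    f = np.asarray(fraction, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise InvalidRatioError(f"atom fraction must lie in (0, 1), got {fraction!r}")
    return _maybe_scalar(f / (1.0 - f))


def delta_to_atom_fraction(delta, r_standard: float = R_PDB):
    """δ¹³C (‰) straight to the ¹³C atom fraction."""
    return ratio_to_atom_fraction(delta_to_ratio(delta, r_standard))


def atom_fraction_to_delta(fraction, r_standard: float = R_PDB):
    """¹³C atom fraction back to δ¹³C (‰)."""
    return ratio_to_delta(atom_fraction_to_ratio(fraction), r_standard)


def pool_13c_mass(c_content, delta, r_standard: float = R_PDB):
    """¹³C mass in a pool, mg per kg soil: C content × atom fraction."""
    c = np.asarray(c_content, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_content must be non-negative")
    return _maybe_scalar(c * delta_to_atom_fraction(delta, r_standard))


def source_contribution(delta_sm, end: IsotopeEndMembers, *, space: str = "delta",
                        warn: bool = True):
    """Percent of a pool's C derived from straw (F_m), by end-member mixing.

    ``space="delta"`` interpolates linearly in δ units,
    F_m = 100·(δ_sm − δ_s)/(δ_m − δ_s).  ``space="atom"`` interpolates in
    ¹³C atom-fraction units, which is exact under mass balance; the two
    differ by well under 2% relative for enrichments up to a few hundred ‰.

    Values outside [0, 100] are returned as-is with a
    :class:`MixingRangeWarning` (measurement noise legitimately produces
    them); they are never clipped.
    """
    if space == "delta":
        num = np.asarray(delta_sm, dtype=float) - end.delta_soil
        den = end.delta_straw - end.delta_soil
    elif space == "atom":
        a_s = delta_to_atom_fraction(end.delta_soil, end.r_standard)
        a_m = delta_to_atom_fraction(end.delta_straw, end.r_standard)
        num = delta_to_atom_fraction(delta_sm, end.r_standard) - a_s
        den = a_m - a_s
    else:
        raise ValueError(f"space must be 'delta' or 'atom', got {space!r}")
    f = 100.0 * num / den
    if warn and np.any((np.asarray(f) < 0) | (np.asarray(f) > 100)):
        warnings.warn("source contribution outside [0, 100]%", MixingRangeWarning,
                      stacklevel=2)
    return _maybe_scalar(f)


def mbc_from_fumigation(c_fumigated, c_nonfumigated, k_ec: float = 0.45):
    """Microbial biomass C from the chloroform-fumigation flush.

    MBC = (C_fumigated − C_nonfumigated) / k_ec, with k_ec the extraction
    efficiency (conventionally 0.45).
    """
    if not 0 < k_ec <= 1:
        raise ValueError(f"k_ec must lie in (0, 1], got {k_ec!r}")
    cf = np.asarray(c_fumigated, dtype=float)
    cn = np.asarray(c_nonfumigated, dtype=float)
    if np.any(cn < 0):
        raise ValueError("extract C contents must be non-negative")
    if np.any(cf < cn):
        raise NegativeFlushError(
            "fumigated extract C below non-fumigated extract C"
        )
    return _maybe_scalar((cf - cn) / k_ec)


def delta_of_difference(c_total, delta_total, c_part, delta_part,
                        r_standard: float = R_PDB):
    """δ¹³C of the remainder when a sub-pool is subtracted from a total.

    Works in ¹³C-mass space: the remainder's ¹³C mass is the total's minus
    the part's, converted back through atom fraction → ratio → δ.  Used for
    the δ¹³C of MaOC (SOC minus POC) and of the fumigation flush
    (fumigated minus non-fumigated extract).
    """
    c_total = float(c_total)
    c_part = float(c_part)
    if not c_total > c_part or c_part < 0:
        raise InfeasibleMassBalanceError(
            f"need c_total > c_part >= 0, got ({c_total}, {c_part})"
        )
    if c_part == 0.0:
        # nothing removed: remainder is the total
        delta_to_ratio(delta_total, r_standard)  # still validate
        return float(delta_total)
    m13_rem = (pool_13c_mass(c_total, delta_total, r_standard)
               - pool_13c_mass(c_part, delta_part, r_standard))
    c_rem = c_total - c_part
    if m13_rem <= 0 or m13_rem >= c_rem:
        raise InfeasibleMassBalanceError(
            "remainder ¹³C mass infeasible: "
            f"{m13_rem!r} mg in {c_rem!r} mg C"
        )
    return atom_fraction_to_delta(m13_rem / c_rem, r_standard)


def maoc_by_difference(soc: pd.Series, poc: pd.Series,
                       r_standard: float = R_PDB) -> pd.Series:
    """Mineral-associated organic C record from SOC minus POC.

    ``soc`` and ``poc`` are rows of the long-format pool table for the same
    (treatment, replicate, day).  Returns a new row with pool "MaOC",
    c_content = SOC − POC and δ¹³C from ¹³C mass balance.
    """
    keys = ["treatment", "replicate", "day"]
    if any(soc[k] != poc[k] for k in keys):
        raise PairingError(
            f"SOC/POC rows disagree on {keys}: "
            f"{[soc[k] for k in keys]} vs {[poc[k] for k in keys]}"
        )
    c_soc = float(soc["c_content_mg_per_kg"])
    c_poc = float(poc["c_content_mg_per_kg"])
    if c_poc > c_soc:
        raise InfeasibleMassBalanceError(
            f"POC {c_poc} exceeds SOC {c_soc} for "
            f"{[soc[k] for k in keys]}"
        )
    if c_poc == c_soc:
        c_maoc, d_maoc = 0.0, float(soc["delta13c_permil"])
    else:
        c_maoc = c_soc - c_poc
        d_maoc = delta_of_difference(
            c_soc, soc["delta13c_permil"], c_poc, poc["delta13c_permil"],
            r_standard,
        )
    out = soc.copy()
    out["pool"] = "MaOC"
    out["c_content_mg_per_kg"] = c_maoc
    out["delta13c_permil"] = d_maoc
    return out


def straw_13c_added(amend: StrawAmendment, end: IsotopeEndMembers) -> float:
    """Gross ¹³C added with the straw, mg per kg soil."""
    return amend.c_added_mg_per_kg * delta_to_atom_fraction(
        amend.delta, end.r_standard
    )


def excess_13c_added(amend: StrawAmendment, end: IsotopeEndMembers) -> float:
    """Excess ¹³C added above the control-soil baseline, mg per kg soil.

    This is the natural denominator of the allocation fraction: the
    numerator (amended-minus-control ¹³C of a pool) measures excess above
    the same baseline.
    """
    a_m = delta_to_atom_fraction(amend.delta, end.r_standard)
    a_s = delta_to_atom_fraction(end.delta_soil, end.r_standard)
    return amend.c_added_mg_per_kg * (a_m - a_s)


def allocation_fraction(c_amended, delta_amended, c_control, delta_control,
                        amend: StrawAmendment, end: IsotopeEndMembers, *,
                        denominator: str = "excess", warn: bool = True):
    """Percent of the added straw C residing in a pool.

    Two self-consistent conventions are offered; with noise-free data both
    return exactly (straw-derived pool C)/(straw C added):

    ``"excess"`` (default)
        excess ¹³C of the amended pool above the matched control's atom
        fraction, c_am · (af_am − af_control), divided by the excess ¹³C
        added with the straw above the soil baseline.

    ``"gross"``
        increase of the pool's ¹³C mass over the control,
        c_am·af_am − c_ctrl·af_ctrl, divided by the gross ¹³C added with
        the straw.  This is the increased-¹³C-over-total-straw-¹³C reading.

    The pairing matters: because the amended pool holds the control's
    native C *plus* straw C, the mass-difference numerator measures gross
    straw ¹³C, while the atom-fraction-difference numerator measures excess
    ¹³C; each must be divided by its like denominator.  Negative values are
    flagged, not clipped.
    """
    af_am = delta_to_atom_fraction(delta_amended, end.r_standard)
    af_ct = delta_to_atom_fraction(delta_control, end.r_standard)
    if denominator == "excess":
        num = np.asarray(c_amended, dtype=float) * (af_am - af_ct)
        denom = excess_13c_added(amend, end)
    elif denominator == "gross":
        num = (pool_13c_mass(c_amended, delta_amended, end.r_standard)
               - pool_13c_mass(c_control, delta_control, end.r_standard))
        denom = straw_13c_added(amend, end)
    else:
        raise ValueError(f"denominator must be 'excess' or 'gross', got {denominator!r}")
    pct = 100.0 * num / denom
    if warn and np.any((np.asarray(pct) < 0) | (np.asarray(pct) > 100)):
        warnings.warn("allocation fraction outside [0, 100]%",
                      MixingRangeWarning, stacklevel=2)
    return _maybe_scalar(pct)


@dataclass
class PartitionResult:
    """Outputs of :func:`partition_table`.

    allocation / contribution are per-(day, pool) summaries
    (columns day, pool, mean, sd, n, flags); replicates carries the
    underlying per-replicate values for downstream per-sample statistics.
    """

    allocation: pd.DataFrame
    contribution: pd.DataFrame
    replicates: pd.DataFrame
    flags: list = field(default_factory=list)


def validate_pool_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format pool table schema and uniqueness."""
    missing_cols = [c for c in POOL_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"pool table missing columns: {missing_cols}")
    bad_pools = set(df["pool"]) - set(KNOWN_POOLS)
    if bad_pools:
        raise ValueError(f"unknown pool labels: {sorted(bad_pools)}")
    bad_treat = set(df["treatment"]) - {"amended", "control"}
    if bad_treat:
        raise ValueError(f"unknown treatments: {sorted(bad_treat)}")
    keys = ["treatment", "replicate", "day", "pool"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(
            f"duplicate (treatment, replicate, day, pool) records: "
            f"{df.loc[dup, keys].values.tolist()[:5]}"
        )
    if (df["c_content_mg_per_kg"] < 0).any():
        raise ValueError("negative c_content in pool table")
    return df


def _derive_missing_maoc(df: pd.DataFrame, r_standard: float) -> pd.DataFrame:
    """Add MaOC rows by SOC − POC wherever MaOC is absent but both exist."""
    have = df[df["pool"] == "MaOC"][["treatment", "replicate", "day"]]
    have_keys = set(map(tuple, have.values))
    soc = df[df["pool"] == "SOC"].set_index(["treatment", "replicate", "day"])
    poc = df[df["pool"] == "POC"].set_index(["treatment", "replicate", "day"])
    new_rows = []
    for key in soc.index.intersection(poc.index):
        if key in have_keys:
            continue
        s = soc.loc[key].copy()
        p = poc.loc[key].copy()
        for k, v in zip(["treatment", "replicate", "day"], key):
            s[k] = v
            p[k] = v
        new_rows.append(maoc_by_difference(s, p, r_standard))
    if new_rows:
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return df


def partition_table(measurements: pd.DataFrame, amend: StrawAmendment,
                    end: IsotopeEndMembers, *, denominator: str = "excess",
                    pools=FRACTION_POOLS) -> PartitionResult:
    """Partition straw-derived C across SOC fractions over time.

    For every (day, pool, replicate), the amended measurement is paired with
    the control measurement at the same day and replicate label; the excess
    ¹³C relative to that control, divided by the ¹³C added with the straw,
    gives the allocation fraction, and end-member mixing with the matched
    control δ¹³C gives the straw contribution F_m to the pool.  Replicates
    are aggregated as mean ± sd; a per-day "total" row sums the four
    fraction pools' allocation.

    Raises :class:`IncompleteDesignError` listing every missing design cell
    if any (treatment, replicate, day, pool) combination is absent.
    """
    df = validate_pool_table(measurements.copy())
    df = _derive_missing_maoc(df, end.r_standard)

    days = sorted(df["day"].unique())
    reps = sorted(df["replicate"].unique())
    want_pools = [p for p in KNOWN_POOLS if p in set(df["pool"]) or p in pools]

    have = set(map(tuple, df[["treatment", "replicate", "day", "pool"]].values))
    need = {(t, r, d, p)
            for t in ("amended", "control")
            for r in reps for d in days for p in want_pools}
    missing = need - have
    if missing:
        raise IncompleteDesignError(missing)

    wide = df.set_index(["treatment", "day", "pool", "replicate"]).sort_index()
    rows = []
    for d in days:
        for p in want_pools:
            for r in reps:
                am = wide.loc[("amended", d, p, r)]
                ct = wide.loc[("control", d, p, r)]
                c_am = float(am["c_content_mg_per_kg"])
                d_am = float(am["delta13c_permil"])
                c_ct = float(ct["c_content_mg_per_kg"])
                d_ct = float(ct["delta13c_permil"])
                alloc = allocation_fraction(
                    c_am, d_am, c_ct, d_ct, amend, end,
                    denominator=denominator, warn=False,
                )
                # Eq.-style two end-member mixing: the control at the matched
                # day is the unamended end member.
                local_end = IsotopeEndMembers(d_ct, amend.delta, end.r_standard)
                f_m = source_contribution(d_am, local_end, warn=False)
                rows.append({
                    "day": d, "pool": p, "replicate": r,
                    "c_amended": c_am, "c_control": c_ct,
                    "m13c_amended": pool_13c_mass(c_am, d_am, end.r_standard),
                    "m13c_control": pool_13c_mass(c_ct, d_ct, end.r_standard),
                    "alloc_pct": alloc, "f_m": f_m,
                })
    replicates = pd.DataFrame(rows)

    def _flags(values, label):
        out_of_range = (values < 0) | (values > 100)
        return f"{label}_out_of_range" if out_of_range.any() else ""

    def _summary(col, label):
        recs = []
        for (d, p), g in replicates.groupby(["day", "pool"], sort=False):
            recs.append({
                "day": d, "pool": p,
                "mean": g[col].mean(), "sd": g[col].std(ddof=1),
                "n": len(g), "flags": _flags(g[col], label),
            })
        return pd.DataFrame(recs)

    allocation = _summary("alloc_pct", "alloc")
    contribution = _summary("f_m", "f_m")

    # per-day totals over the four fraction pools, computed per replicate so
    # the sd is the spread of replicate totals; the mean equals the sum of
    # the four pool means exactly.
    frac = replicates[replicates["pool"].isin(pools)]
    totals = (frac.groupby(["day", "replicate"])["alloc_pct"].sum()
                  .groupby("day"))
    total_rows = pd.DataFrame({
        "day": totals.mean().index,
        "pool": "total",
        "mean": totals.mean().values,
        "sd": totals.std(ddof=1).values,
        "n": totals.count().values,
        "flags": "",
    })
    allocation = pd.concat([allocation, total_rows], ignore_index=True)
    allocation = allocation.sort_values(["day", "pool"]).reset_index(drop=True)
    contribution = contribution.sort_values(["day", "pool"]).reset_index(drop=True)

    flags = sorted({f for f in allocation["flags"] if f}
                   | {f for f in contribution["flags"] if f})
    return PartitionResult(allocation, contribution, replicates, flags)
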