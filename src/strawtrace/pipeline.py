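"""Run configuration and the simulate → partition → link → report stages.

Each stage is a plain function taking a validated :class:`RunConfig`; the
command-line layer in :mod:`strawtrace.cli` is a thin wrapper around these.
A single root seed deterministically derives every per-stage random stream,
so identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as stio
from .community import (
    bray_curtis_matrix,
    euclidean_matrix,
    mantel,
    relative_abundance,
    spearman_table,
)
from .isotope import (
    FRACTION_POOLS,
    IsotopeEndMembers,
    MixingRangeWarning,
    StrawAmendment,
    partition_table,
)
from .simulate import DEFAULT_AMENDMENT, DEFAULT_SOIL_DELTA, SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown run-configuration key."""


@dataclass(frozen=True)
class PartitionOptions:
    k_ec: float = 0.45
    denominator: str = "excess"
    delta_soil: float = DEFAULT_SOIL_DELTA
    delta_straw: float = DEFAULT_AMENDMENT["delta"]
    amendment: dict = field(default_factory=lambda: dict(DEFAULT_AMENDMENT))

    def __post_init__(self):
        if self.denominator not in ("excess", "gross"):
            raise ConfigError(f"denominator must be excess|gross, got {self.denominator!r}")
        if not 0 < self.k_ec <= 1:
            raise ConfigError(f"k_ec must lie in (0, 1], got {self.k_ec}")

    @property
    def end_members(self) -> IsotopeEndMembers:
        return IsotopeEndMembers(self.delta_soil, self.delta_straw)

    @property
    def straw(self) -> StrawAmendment:
        return StrawAmendment(**self.amendment)


@dataclass(frozen=True)
class LinkOptions:
    n_perm: int = 999
    method: str = "spearman"
    distance: str = "braycurtis"
    fraction_value: str = "alloc_pct"
    arm: str = "amended"
    pool_replicates: bool = False   # average replicates per day before distances

    def __post_init__(self):
        if self.method not in ("spearman", "pearson"):
            raise ConfigError(f"method must be spearman|pearson, got {self.method!r}")
        if self.distance not in ("braycurtis", "euclidean"):
            raise ConfigError(f"distance must be braycurtis|euclidean, got {self.distance!r}")
        if self.fraction_value not in ("alloc_pct", "f_m"):
            raise ConfigError(f"fraction_value must be alloc_pct|f_m, got {self.fraction_value!r}")
        if self.arm not in ("amended", "control"):
            raise ConfigError(f"arm must be amended|control, got {self.arm!r}")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for all pipeline stages."""

    seed: int = 0
    out_dir: str = "strawtrace_out"
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    partition: PartitionOptions = field(default_factory=PartitionOptions)
    link: LinkOptions = field(default_factory=LinkOptions)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, section):
            data = dict(raw.pop(section, {}) or {})
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(data) - names
            if bad:
                raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
            try:
                return klass(**data)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid '{section}' config: {exc}") from exc

        sim = build(SimulationConfig, "simulate")
        part = build(PartitionOptions, "partition")
        link = build(LinkOptions, "link")
        seed = int(raw.pop("seed", 0))
        sim = sim.with_seed(seed)
        return cls(seed=seed,
                   out_dir=str(raw.pop("out_dir", "strawtrace_out")),
                   log_level=str(raw.pop("log_level", "INFO")),
                   paths={str(k): str(v) for k, v in (raw.pop("paths", {}) or {}).items()},
                   simulate=sim, partition=part, link=link)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw or {})

    def with_overrides(self, seed=None, out_dir=None) -> "RunConfig":
        rc = self
        if seed is not None:
            rc = dataclasses.replace(rc, seed=int(seed),
                                     simulate=rc.simulate.with_seed(int(seed)))
        if out_dir is not None:
            rc = dataclasses.replace(rc, out_dir=str(out_dir))
        return rc

    def path(self, key: str, default_name: str) -> Path:
        if key in self.paths:
            return Path(self.paths[key])
        return Path(self.out_dir) / default_name

    def header(self) -> str:
        return stio.provenance_header(self.seed, self.simulate.config_hash())


def run_simulate(rc: RunConfig) -> dict:
    """Generate the simulated dataset files in the output directory."""
    return generate_dataset(rc.simulate, rc.out_dir)


def run_partition(rc: RunConfig) -> dict:
    """Partition straw-derived C from the pool table; write summary tables."""
    pools_path = rc.path("pools", "pools.tsv")
    if not Path(pools_path).exists():
        raise FileNotFoundError(f"pool table not found: {pools_path}")
    df = stio.read_pool_table(pools_path)
    if not (df["treatment"] == "amended").any():
        raise ValueError("no amended-treatment records in pool table")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MixingRangeWarning)
        result = partition_table(df, rc.partition.straw, rc.partition.end_members,
                                 denominator=rc.partition.denominator)
    if result.flags:
        logger.warning("partition flags raised: %s", result.flags)
    header = rc.header()
    out = {
        "allocation": stio.write_table(result.allocation, rc.out_dir,
                                       "allocation.tsv", header),
        "contribution": stio.write_table(result.contribution, rc.out_dir,
                                         "contribution.tsv", header),
        "allocation_by_replicate": stio.write_table(
            result.replicates, rc.out_dir, "allocation_by_replicate.tsv", header),
    }
    return out


def _fraction_matrix(reps: pd.DataFrame, metadata: pd.DataFrame,
                     value_col: str) -> pd.DataFrame:
    """Per-sample straw-derived fraction vectors, aligned to sample ids."""
    wide = reps[reps["pool"].isin(FRACTION_POOLS)].pivot_table(
        index=["day", "replicate"], columns="pool", values=value_col)
    rows = {}
    missing = []
    for _, m in metadata.iterrows():
        key = (m["day"], m["replicate"])
        if key not in wide.index:
            missing.append(m["sample"])
            continue
        rows[m["sample"]] = wide.loc[key, list(FRACTION_POOLS)]
    if missing:
        raise ValueError(f"no allocation values for samples: {missing}")
    return pd.DataFrame(rows).T[list(FRACTION_POOLS)]


def run_link(rc: RunConfig) -> dict:
    """Mantel correlation and the genus × fraction Spearman table."""
    taxa_path = rc.path("taxa", "taxa.tsv")
    meta_path = rc.path("metadata", "metadata.tsv")
    reps_path = rc.path("allocation_by_replicate", "allocation_by_replicate.tsv")
    for p in (taxa_path, meta_path, reps_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"required input not found: {p}")
    counts = (stio.read_biom(taxa_path) if str(taxa_path).endswith(".biom")
              else stio.read_taxa_table(taxa_path))
    metadata = stio.read_metadata(meta_path)
    reps = stio.read_table(reps_path)

    meta = metadata[metadata["treatment"] == rc.link.arm]
    missing_samples = sorted(set(meta["sample"]) - set(counts.columns))
    if missing_samples:
        raise ValueError(f"samples in metadata but not in taxa table: {missing_samples}")
    meta = meta.sort_values(["day", "replicate"]).reset_index(drop=True)
    sample_ids = list(meta["sample"])
    if len(sample_ids) < 4:
        raise ValueError(f"too few samples for the Mantel test: {len(sample_ids)} < 4")

    rel = relative_abundance(counts[sample_ids])
    fractions = _fraction_matrix(reps, meta, rc.link.fraction_value).loc[sample_ids]

    if rc.link.pool_replicates:
        day_of = meta.set_index("sample")["day"]
        community_samples = rel.T.groupby(rel.columns.map(day_of)).mean()
        fractions = fractions.groupby(fractions.index.map(day_of)).mean()
        labels = [f"day{d}" for d in community_samples.index]
        community_samples.index = labels
        fractions.index = labels
    else:
        community_samples = rel.T

    d_community = bray_curtis_matrix(community_samples)
    if rc.link.distance == "braycurtis":
        frac_vals = fractions.copy()
        if (frac_vals.values < 0).any():
            logger.warning("negative fraction values shifted to zero for "
                           "Bray-Curtis distances")
            frac_vals = frac_vals.clip(lower=0.0)
        d_fractions = bray_curtis_matrix(frac_vals)
    else:
        d_fractions = euclidean_matrix(fractions)

    seed = np.random.SeedSequence([rc.seed, 404])
    res = mantel(d_community, d_fractions, n_perm=rc.link.n_perm,
                 method=rc.link.method, seed=seed)
    mantel_df = pd.DataFrame([{
        "comparison": f"community_vs_straw_derived_{rc.link.fraction_value}",
        "arm": rc.link.arm, "r": res.r, "p": res.p,
        "n_perm": res.n_perm, "method": res.method, "n_samples": res.n,
    }])

    genus_rel = community_samples.T  # taxa × (samples or pooled days)
    table = spearman_table(genus_rel, fractions)
    spearman_df = table.to_frame().reset_index()

    header = rc.header()
    out = {
        "mantel": stio.write_table(mantel_df, rc.out_dir, "mantel.tsv", header),
        "spearman_table": stio.write_table(spearman_df, rc.out_dir,
                                           "spearman_table.tsv", header),
    }
    return out


def simulate_and_link(cfg: SimulationConfig, *, n_perm: int = 999,
                      method: str = "spearman", fraction_value: str = "alloc_pct",
                      arm: str = "amended", mantel_seed=None):
    """Full in-memory round trip: simulate → partition → Mantel linkage.

    Returns the :class:`~strawtrace.community.MantelResult` for the chosen
    arm's community distances against its straw-derived fraction distances.
    Convenience for calibration studies that do not need files on disk.
    """
    from .simulate import simulate_community, simulate_pools

    measurements, truth = simulate_pools(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MixingRangeWarning)
        res = partition_table(measurements, cfg.straw, cfg.end_members)
    counts, metadata = simulate_community(cfg, truth)
    meta = (metadata[metadata["treatment"] == arm]
            .sort_values(["day", "replicate"]).reset_index(drop=True))
    sample_ids = list(meta["sample"])
    rel = relative_abundance(counts[sample_ids])
    fractions = _fraction_matrix(res.replicates, meta, fraction_value)
    fractions = fractions.loc[sample_ids].clip(lower=0.0)
    d_comm = bray_curtis_matrix(rel.T)
    d_frac = bray_curtis_matrix(fractions)
    if mantel_seed is None:
        mantel_seed = np.random.SeedSequence([cfg.seed, 404])
    return mantel(d_comm, d_frac, n_perm=n_perm, method=method,
                  seed=mantel_seed)


def run_report(rc: RunConfig) -> Path:
    """Merge the stage outputs into one human-readable summary file."""
    needed = {
        "allocation": rc.path("allocation", "allocation.tsv"),
        "contribution": rc.path("contribution", "contribution.tsv"),
        "mantel": rc.path("mantel", "mantel.tsv"),
        "spearman_table": rc.path("spearman_table", "spearman_table.tsv"),
    }
    missing = [f"{k} ({v})" for k, v in needed.items() if not Path(v).exists()]
    if missing:
        raise FileNotFoundError(f"missing upstream outputs: {missing}")
    alloc = stio.read_table(needed["allocation"])
    contrib = stio.read_table(needed["contribution"])
    mantel_df = stio.read_table(needed["mantel"])
    spearman_df = stio.read_table(needed["spearman_table"])

    lines = [rc.header(), "", "== Straw-C allocation (% of added straw C) =="]
    totals = alloc[alloc["pool"] == "total"].sort_values("day")
    for _, r in totals.iterrows():
        lines.append(f"day {int(r['day']):>4}: total conversion "
                     f"{r['mean']:.2f} ± {r['sd']:.2f} % (n={int(r['n'])})")
    lines.append("")
    lines.append("== Per-pool allocation ==")
    lines.append(alloc.to_string(index=False,
                                 float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    lines.append("== Straw contribution to pool C (F_m, %) ==")
    lines.append(contrib.to_string(index=False,
                                   float_format=lambda v: f"{v:.3f}"))
    lines.append("")
    lines.append("== Community linkage ==")
    lines.append(mantel_df.to_string(index=False,
                                     float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    lines.append("== Genus × straw-derived fraction Spearman table ==")
    lines.append(spearman_df.to_string(index=False))
    lines.append("")
    path = Path(rc.out_dir) / "report.txt"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines), encoding="utf-8")
    return path
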