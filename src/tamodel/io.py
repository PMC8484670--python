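"""Loading, saving and pipeline orchestration.

The canonical exchange format is a long-format TSV with columns
``pair, role, time_h, value`` where role is ``toxin`` or ``antitoxin`` and
``value`` is the *raw* expression value; on loading, values are multiplied
by the scale constant c (default 1e5) so fits operate on O(1)-O(100)
numbers.  GEO series matrices vary in layout, so projecting a real
expression matrix into this format is left to a documented helper table
(``PAIR_GENES``) mapping each of the 11 E. coli TA operons to its
antitoxin and toxin gene; no network access is performed by this package.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import (
    build_matrix,
    cluster_report,
    dbscan_cluster,
    format_report,
    pca_embed,
)
from .fitting import FitResult, InitialConditionMode, OptConfig, TimeCourse, fit_all
from .model import SolverConfig, VARIANT_NAMES
from .selection import best_model, collective_selection
from .synthetic import GeneratorConfig, generate_dataset

__all__ = [
    "Dataset",
    "RunConfig",
    "PAIR_GENES",
    "read_timecourses",
    "write_timecourses",
    "fit_results_to_frame",
    "run_pipeline",
]

logger = logging.getLogger("tamodel")

#: The 11 well-characterised E. coli type II TA operons this analysis
#: targets, as (antitoxin gene, toxin gene).  Labels follow the
#: antitoxin-toxin convention.  (ydaT-ydaS annotation is still debated in
#: the literature; the label order here is a naming convention only.)
PAIR_GENES: dict[str, tuple[str, str]] = {
    "dinJ-yafQ": ("dinJ", "yafQ"),
    "relB-relE": ("relB", "relE"),
    "yafN-yafO": ("yafN", "yafO"),
    "higA-higB": ("higA", "higB"),
    "hipB-hipA": ("hipB", "hipA"),
    "hicB-hicA": ("hicB", "hicA"),
    "mqsA-mqsR": ("mqsA", "mqsR"),
    "yefM-yoeB": ("yefM", "yoeB"),
    "ydaT-ydaS": ("ydaT", "ydaS"),
    "ymcE-gnsA": ("ymcE", "gnsA"),
    "yfjZ-ypjF": ("yfjZ", "ypjF"),
}


@dataclass(frozen=True)
class Dataset:
    """A keyed collection of time courses plus provenance."""

    timecourses: tuple[TimeCourse, ...]
    provenance: str
    scale_c: float = 1e5

    def __post_init__(self):
        labels = [tc.pair_label for tc in self.timecourses]
        if len(set(labels)) != len(labels):
            raise ValueError("pair labels must be unique")
        grids = {tuple(tc.times.tolist()) for tc in self.timecourses}
        if len(grids) > 1:
            logger.warning(
                "dataset %s: pairs do not share a common time grid (%d grids)",
                self.provenance, len(grids),
            )

    def __iter__(self):
        return iter(self.timecourses)

    def __len__(self):
        return len(self.timecourses)

    def __getitem__(self, pair_label: str) -> TimeCourse:
        for tc in self.timecourses:
            if tc.pair_label == pair_label:
                return tc
        raise KeyError(pair_label)

    @property
    def pair_labels(self) -> tuple[str, ...]:
        return tuple(tc.pair_label for tc in self.timecourses)


_ROLES = ("antitoxin", "toxin")


def read_timecourses(path: str | Path, scale_c: float = 1e5) -> Dataset:
    """Load the long-format TSV and scale raw values by ``scale_c``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"pair", "role", "time_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad_role = df[~df["role"].isin(_ROLES)]
    if not bad_role.empty:
        raise ValueError(
            f"{path}: invalid role(s) {sorted(bad_role['role'].unique())} "
            f"at row(s) {list(bad_role.index[:5] + 2)}"  # +2: header + 1-based
        )
    neg = df[df["value"] < 0]
    if not neg.empty:
        raise ValueError(
            f"{path}: negative value(s) at row(s) {list(neg.index[:5] + 2)}"
        )
    dup = df.duplicated(subset=["pair", "role", "time_h"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (pair, role, time_h) at row(s) "
            f"{list(df.index[dup][:5] + 2)}"
        )
    timecourses = []
    for pair, grp in df.groupby("pair", sort=True):
        roles = set(grp["role"])
        if roles != set(_ROLES):
            raise ValueError(
                f"{path}: pair {pair!r} must have both roles, found {sorted(roles)}"
            )
        anti = grp[grp["role"] == "antitoxin"].sort_values("time_h")
        tox = grp[grp["role"] == "toxin"].sort_values("time_h")
        if not np.array_equal(anti["time_h"].values, tox["time_h"].values):
            raise ValueError(f"{path}: pair {pair!r}: curves disagree on timepoints")
        timecourses.append(
            TimeCourse(
                pair_label=str(pair),
                times=anti["time_h"].to_numpy(float),
                antitoxin_values=anti["value"].to_numpy(float) * scale_c,
                toxin_values=tox["value"].to_numpy(float) * scale_c,
                scale_applied=scale_c,
            )
        )
    return Dataset(tuple(timecourses), provenance=str(path), scale_c=scale_c)


def write_timecourses(
    dataset: Dataset | Iterable[TimeCourse],
    path: str | Path,
    header_comment: str | None = None,
) -> Path:
    """Write the long-format TSV, storing values back on the raw scale."""
    path = Path(path)
    tcs = list(dataset)
    rows = []
    for tc in tcs:
        for role, values in (("antitoxin", tc.antitoxin_values), ("toxin", tc.toxin_values)):
            for t, v in zip(tc.times, values):
                rows.append(
                    {
                        "pair": tc.pair_label,
                        "role": role,
                        "time_h": t,
                        "value": v / tc.scale_applied,
                    }
                )
    df = pd.DataFrame(rows, columns=["pair", "role", "time_h", "value"])
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def fit_results_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_record() for f in fits])


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for one full pipeline run.

    Exactly one of ``input_path`` (long-format TSV) or ``generator``
    (synthetic dataset settings) supplies the data.  All seeds are explicit
    and the resolved config is serialised next to the outputs.
    """

    output_dir: str
    input_path: str | None = None
    generator: GeneratorConfig | None = None
    variants: tuple[str, ...] = VARIANT_NAMES
    ic_mode: str = "zero_zero_c0"
    scale_c: float = 1e5
    opt: OptConfig = field(default_factory=OptConfig)
    criterion: str = "bic"
    eps: float = 0.8
    min_samples: int = 3
    preprocessing: str = "log10_standardize"
    master_seed: int = 0
    log_level: str = "INFO"

    def to_flat_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "input_path": self.input_path,
            "variants": list(self.variants),
            "ic_mode": self.ic_mode,
            "scale_c": self.scale_c,
            "criterion": self.criterion,
            "eps": self.eps,
            "min_samples": self.min_samples,
            "preprocessing": self.preprocessing,
            "master_seed": self.master_seed,
            "log_level": self.log_level,
            "opt_n_hops": self.opt.n_hops,
            "opt_hop_step": self.opt.hop_step,
            "opt_local_maxiter": self.opt.local_maxiter,
            "opt_n_starts": self.opt.n_starts,
            "opt_solver_rtol": self.opt.solver.rtol,
            "opt_solver_atol": self.opt.solver.atol,
        }
        if self.generator is not None:
            g = self.generator
            d.update(
                {
                    "gen_n_central": g.n_central,
                    "gen_n_outliers": g.n_outliers,
                    "gen_n_times": g.n_times,
                    "gen_t_start": g.t_start,
                    "gen_t_end": g.t_end,
                    "gen_noise_model": g.noise_model,
                    "gen_noise_sigma": g.noise_sigma,
                    "gen_scale_c": g.scale_c,
                    "gen_displacement_decades": g.displacement_decades,
                    "gen_n_displaced_params": g.n_displaced_params,
                    "gen_master_seed": g.master_seed,
                }
            )
        return d

    @classmethod
    def from_flat_dict(cls, d: Mapping) -> "RunConfig":
        gen = None
        if any(k.startswith("gen_") for k in d):
            gen = GeneratorConfig(
                n_central=int(d.get("gen_n_central", 7)),
                n_outliers=int(d.get("gen_n_outliers", 4)),
                n_times=int(d.get("gen_n_times", 10)),
                t_start=float(d.get("gen_t_start", 0.0)),
                t_end=float(d.get("gen_t_end", 10.0)),
                noise_model=str(d.get("gen_noise_model", "lognormal")),
                noise_sigma=float(d.get("gen_noise_sigma", 0.0)),
                scale_c=float(d.get("gen_scale_c", 1e5)),
                displacement_decades=float(d.get("gen_displacement_decades", 2.0)),
                n_displaced_params=int(d.get("gen_n_displaced_params", 3)),
                master_seed=int(d.get("gen_master_seed", d.get("master_seed", 0))),
            )
        opt = OptConfig(
            n_hops=int(d.get("opt_n_hops", 50)),
            hop_step=float(d.get("opt_hop_step", 0.5)),
            local_maxiter=int(d.get("opt_local_maxiter", 2000)),
            n_starts=int(d.get("opt_n_starts", 1)),
            solver=SolverConfig(
                rtol=float(d.get("opt_solver_rtol", 1e-6)),
                atol=float(d.get("opt_solver_atol", 1e-8)),
            ),
            ic_mode=InitialConditionMode(str(d.get("ic_mode", "zero_zero_c0"))),
        )
        return cls(
            output_dir=str(d["output_dir"]),
            input_path=d.get("input_path"),
            generator=gen,
            variants=tuple(d.get("variants", VARIANT_NAMES)),
            ic_mode=str(d.get("ic_mode", "zero_zero_c0")),
            scale_c=float(d.get("scale_c", 1e5)),
            opt=opt,
            criterion=str(d.get("criterion", "bic")),
            eps=float(d.get("eps", 0.8)),
            min_samples=int(d.get("min_samples", 3)),
            preprocessing=str(d.get("preprocessing", "log10_standardize")),
            master_seed=int(d.get("master_seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"master_seed={cfg.master_seed} config_hash={cfg.config_hash()}"


def run_pipeline(cfg: RunConfig) -> dict[str, Path | None]:
    """Execute fit -> selection -> clustering and write all artifacts.

    Produces, under ``cfg.output_dir``: the input data TSV, a fits TSV and
    JSON-lines file, the collective selection table, the cluster report
    (TSV + text), the resolved config and a log.  Stage failures are
    recorded in the log; downstream stages are skipped with an explanation
    and the corresponding artifact paths are returned as None.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    artifacts: dict[str, Path | None] = {"log": log_path}
    try:
        with open(out / "resolved_config.yaml", "w") as fh:
            fh.write(f"# {_header(cfg)}\n")
            yaml.safe_dump(cfg.to_flat_dict(), fh, sort_keys=True)
        artifacts["config"] = out / "resolved_config.yaml"

        if cfg.input_path is not None:
            dataset = read_timecourses(cfg.input_path, cfg.scale_c)
        elif cfg.generator is not None:
            tcs, truth = generate_dataset(cfg.generator)
            dataset = Dataset(
                tuple(tcs), provenance=f"generator(seed={cfg.generator.master_seed})",
                scale_c=cfg.generator.scale_c,
            )
            truth_json = {
                e.pair_label: {
                    "planted_label": e.planted_label,
                    "params": e.params.to_dict(),
                }
                for e in truth.entries
            }
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(truth_json, fh, indent=1)
            artifacts["ground_truth"] = out / "ground_truth.json"
        else:
            raise ValueError("RunConfig needs input_path or generator")
        write_timecourses(dataset, out / "data.tsv", header_comment=_header(cfg))
        artifacts["data"] = out / "data.tsv"

        logger.info("fitting %d pairs x %d variants", len(dataset), len(cfg.variants))
        fits = fit_all(
            dataset,
            variants=list(cfg.variants),
            opt=cfg.opt,
            seed=cfg.master_seed,
        )
        fits_df = fit_results_to_frame(fits)
        with open(out / "fits.tsv", "w") as fh:
            fh.write(f"# {_header(cfg)}\n")
            fits_df.to_csv(fh, sep="\t", index=False)
        with open(out / "fits.jsonl", "w") as fh:
            for f in fits:
                fh.write(json.dumps(f.to_record()) + "\n")
        artifacts["fits"] = out / "fits.tsv"
    except Exception:
        logger.exception("fitting stage failed; skipping selection and clustering")
        logger.removeHandler(handler)
        handler.close()
        artifacts.update({"selection": None, "clusters": None})
        return artifacts

    try:
        rows = collective_selection(fits, criterion=cfg.criterion)
        sel_df = pd.DataFrame([r.to_record() for r in rows])
        with open(out / "selection.tsv", "w") as fh:
            fh.write(f"# {_header(cfg)}\n")
            sel_df.to_csv(fh, sep="\t", index=False)
        artifacts["selection"] = out / "selection.tsv"
        logger.info(
            "best model by %s: %s", cfg.criterion, best_model(rows, cfg.criterion)
        )
    except Exception:
        logger.exception("selection stage failed")
        artifacts["selection"] = None

    try:
        full_fits = [f for f in fits if f.variant_name == "full"]
        if not full_fits:
            raise ValueError("clustering requires full-model fits in the variant list")
        matrix = build_matrix(full_fits, preprocessing=cfg.preprocessing)
        embedding = pca_embed(matrix)
        assignment = dbscan_cluster(embedding, eps=cfg.eps, min_samples=cfg.min_samples)
        report = cluster_report(assignment, embedding)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write(f"# {_header(cfg)}\n")
            report["table"].to_csv(fh, sep="\t", index=False)
        (out / "cluster_report.txt").write_text(
            f"# {_header(cfg)}\n" + format_report(report) + "\n"
        )
        artifacts["clusters"] = out / "clusters.tsv"
        artifacts["cluster_report"] = out / "cluster_report.txt"
    except Exception:
        logger.exception("clustering stage failed")
        artifacts["clusters"] = None
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts
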