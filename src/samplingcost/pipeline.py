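"""End-to-end demonstration pipeline: generate -> fit -> superlinearity.

For each configured linking family the pipeline generates a synthetic
reading-time dataset, fits the linear control and the location-scale curve,
computes the superlinearity of the fitted mean curve, and writes a JSON
report (plus per-family TSV curve tables and optional plots).  Identical
configurations produce byte-identical JSON reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .curvefit import fit_linear_control, fit_location_scale
from .linking import LinkingFunction
from .superlinearity import superlinearity_of_fit
from .synthetic import GeneratorConfig, generate_rt_dataset
from .tables import write_rt_table

__all__ = ["RunConfig", "run_demo_pipeline", "load_config", "dump_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of the demo pipeline.

    ``families`` maps a label to linking-function spec dicts of the form
    ``{"family": ..., "params": {...}}``.  Every stochastic stage derives
    its seed from ``seed``, so a run is a pure function of this object.
    """

    families: dict = field(
        default_factory=lambda: {
            "linear": {"family": "linear", "params": {"alpha": 250.0, "beta": 25.0}},
            "exponential": {"family": "exponential", "params": {"c": 40.0}},
        }
    )
    n_subjects: int = 40
    n_items: int = 800
    seed: int = 0
    basis_dim: int = 6
    fit_scale: bool = True
    adjust_subjects: bool = True
    adjust_spillover: bool = True
    make_plots: bool = False
    outdir: str = "demo_output"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def digest(self) -> str:
        """Digest of the scientific configuration (output location and
        plotting flags excluded, so reports are comparable across runs)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("make_plots", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (JSON is valid YAML)."""
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def run_demo_pipeline(cfg: RunConfig) -> dict:
    """Run the full generate/fit/measure pipeline; returns the report dict.

    Writes ``report.json``, per-family data and curve TSVs, and (optionally)
    plots into ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "families": {},
    }
    for idx, (label, spec) in enumerate(sorted(cfg.families.items())):
        try:
            link = LinkingFunction(spec["family"], dict(spec["params"]))
            gen = GeneratorConfig(
                linking=link,
                n_subjects=cfg.n_subjects,
                n_items=cfg.n_items,
                seed=cfg.seed + 1000 * idx,
            )
            data = generate_rt_dataset(gen)
            write_rt_table(data, outdir / f"{label}_data.tsv")

            control = fit_linear_control(
                data,
                adjust_subjects=cfg.adjust_subjects,
                adjust_spillover=cfg.adjust_spillover,
            )
            fit = fit_location_scale(
                data,
                basis_dim=cfg.basis_dim,
                adjust_subjects=cfg.adjust_subjects,
                adjust_spillover=cfg.adjust_spillover,
                fit_scale=cfg.fit_scale,
            )
            sl = superlinearity_of_fit(fit)

            import pandas as pd

            pd.DataFrame({"grid": fit.grid, "mu": fit.mu, "log_sd": fit.log_sd}).to_csv(
                outdir / f"{label}_curve.tsv", sep="\t", index=False
            )
            if cfg.make_plots:
                _plot_family(label, data, fit, outdir)

            report["families"][label] = {
                "linking": spec,
                "beta_mean": control.beta_mean,
                "se_beta_mean": control.se_beta_mean,
                "beta_logsd": control.beta_logsd,
                "se_beta_logsd": control.se_beta_logsd,
                "superlinearity": sl.superlinearity,
                "slope_low": sl.slope_low,
                "slope_high": sl.slope_high,
                "fit_converged": fit.converged,
                "fit_iterations": fit.iterations,
            }
        except Exception as exc:  # noqa: BLE001 - stage-labelled propagation
            raise RuntimeError(f"demo pipeline failed at family {label!r}: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _plot_family(label: str, data, fit, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    sub = data.frame.sample(min(len(data.frame), 4000), random_state=0)
    axes[0].plot(sub["surprisal"], sub["rt"], ".", ms=2, alpha=0.25, color="grey")
    axes[0].plot(fit.grid, fit.mu, color="C0", lw=2)
    axes[0].set_ylabel("reading time (ms)")
    axes[0].set_title(f"{label}: mean RT and log-SD vs surprisal")
    axes[1].plot(fit.grid, fit.log_sd, color="C3", lw=2)
    axes[1].set_xlabel("surprisal (nats)")
    axes[1].set_ylabel("log SD (ln ms)")
    fig.tight_layout()
    fig.savefig(outdir / f"{label}_curves.png", dpi=120)
    plt.close(fig)
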