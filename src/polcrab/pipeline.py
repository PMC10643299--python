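"""End-to-end behavioural analysis: trials in, fits/figures/JSON out.

For every species x modality group the pipeline applies the pre-stimulus
retreat exclusion, fits sigmoid contrast-response curves per polarity (where
at least four levels exist), the habituation line, the random-intercept
logistic model with LRTs for contrast and order, and the polarity-split
models, then renders a three-panel report (contrast response, order response,
behaviour-onset timing).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bhv
from . import glmm
from .io import RunConfig
from .synthdata import ObserverModel, simulate_trials

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0.0"


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sigmoid_branch(levels, props, ns, polarity):
    """Fit one polarity branch on |contrast| (controls anchor both branches)."""
    keep = levels >= 0 if polarity == "positive" else levels <= 0
    x = np.abs(levels[keep])
    if np.unique(x).size < 4:
        return None  # mirrors "where possible"
    fit = bhv.fit_sigmoid(x, props[keep], n_trials=ns[keep])
    return dataclasses.asdict(fit)


def analyze_group(trials, window=None, quadratic=False):
    """All fitted quantities for one species x modality trial set."""
    kept, excluded = bhv.apply_exclusions(trials)
    logger.info("kept %d trials, excluded %d (pre-stimulus full retreat)", len(kept), len(excluded))
    levels, props, ns = bhv.response_table(kept, window)

    out = {
        "n_trials": len(kept),
        "n_excluded": len(excluded),
        "n_crabs": len({t.crab_id for t in kept}),
        "contrast_levels": levels.tolist(),
        "response_proportions": props.tolist(),
        "n_per_level": ns.tolist(),
    }

    out["sigmoid"] = {
        "positive": _sigmoid_branch(levels, props, ns, "positive"),
        "negative": _sigmoid_branch(levels, props, ns, "negative"),
    }
    out["half_max_thresholds"] = {
        pol: (fit["x50"] if fit and fit["converged"] else None)
        for pol, fit in out["sigmoid"].items()
    }

    orders = [t.order for t in kept]
    responses = [float(bhv.score_response(t, window)) for t in kept]
    hab = bhv.fit_habituation(orders, responses)
    out["habituation"] = {"h": hab.h, "intercept": hab.intercept}

    effects = ("contrast", "contrast2", "order") if quadratic else ("contrast", "order")
    lrt_table = {}
    for effect in ("contrast", "order"):
        full, reduced, res = glmm.effect_lrt(kept, effect, effects, window)
        lrt_table[effect] = {
            "chi2": res.chi2,
            "df": res.df,
            "p": res.p,
            "coefficient": full.coefficients.get(effect),
        }
        if effect == "contrast":
            out["glmm"] = {
                "coefficients": full.coefficients,
                "random_intercept_sd": full.random_intercept_sd,
                "loglik": full.loglik,
                "n_obs": full.n_obs,
                "n_groups": full.n_groups,
                "converged": full.converged,
            }
            if not full.converged:
                logger.warning("GLMM convergence flag is False for the full model")
    out["lrt"] = lrt_table

    splits = glmm.polarity_split_fits(kept, window)
    out["polarity_splits"] = {
        label: (
            {"chi2": d["lrt"].chi2, "df": d["lrt"].df, "p": d["lrt"].p}
            if not d["non_identifiable"]
            else {"non_identifiable": True}
        )
        for label, d in splits.items()
    }
    return out, kept


def _figure(group_key, result, kept, window, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    levels = np.array(result["contrast_levels"])
    props = np.array(result["response_proportions"])
    axes[0].plot(levels, props, "ko")
    for pol, sign in (("positive", 1), ("negative", -1)):
        fit = result["sigmoid"][pol]
        if fit:
            xs = np.linspace(0, abs(levels).max(), 100)
            axes[0].plot(
                sign * xs,
                bhv.four_param_logistic(xs, fit["bottom"], fit["top"], fit["x50"], fit["slope"]),
                "r-",
            )
            if fit["converged"]:
                axes[0].axvline(sign * fit["x50"], color="r", ls=":")
    axes[0].set(xlabel="contrast", ylabel="response probability", ylim=(-0.05, 1.05))

    orders = np.array([t.order for t in kept])
    resp = np.array([float(bhv.score_response(t, window)) for t in kept])
    olev = np.unique(orders)
    omeans = [resp[orders == o].mean() for o in olev]
    axes[1].plot(olev, omeans, "ko")
    hab = result["habituation"]
    axes[1].plot(olev, hab["intercept"] + hab["h"] * olev, "b-")
    axes[1].set(xlabel="stimulus order", ylabel="response probability", ylim=(-0.05, 1.05))
    axes[1].set_title(f"h = {hab['h']:.3f}")

    for kind, colour in (("stop", "red"), ("retreat", "gold"), ("walk", "blue")):
        onsets = [o for t in kept for k, o in t.behaviours if k == kind]
        if onsets:
            axes[2].hist(onsets, bins=20, color=colour, alpha=0.6, label=kind)
    axes[2].set(xlabel="onset (s from loom start)", ylabel="count")
    axes[2].legend(fontsize=7)
    fig.suptitle(" / ".join(group_key))
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full behavioural analysis described by ``config``.

    Returns the results bundle; writes ``results.json``, per-group CSV
    summaries and figures under ``config.out_dir``.  A stage failure raises
    :class:`PipelineError` naming the stage, after writing partial results.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.trials_csv:
        from .io import read_trials

        trials = read_trials(config.trials_csv)
    elif config.synthdata is not None:
        sc = config.synthdata
        model = ObserverModel(**sc.observer.model_dump(), seed=config.seed)
        trials = simulate_trials(
            model, sc.n_crabs, sc.contrast_set, modality=sc.modality, species=sc.species
        )
    else:
        raise PipelineError("input", "config must provide trials_csv or a synthdata block")

    groups: dict[tuple, list] = {}
    for t in trials:
        groups.setdefault((t.species, t.modality), []).append(t)

    results = {"schema_version": SCHEMA_VERSION, "seed": config.seed, "groups": {}}
    for key, group_trials in sorted(groups.items()):
        name = f"{key[0]}:{key[1]}"
        quadratic = name in config.behaviour.quadratic_for
        window = config.behaviour.window or bhv.default_window(key[0])
        try:
            result, kept = analyze_group(group_trials, window, quadratic)
        except Exception as exc:  # preserve partial results
            (out_dir / "results.json").write_text(json.dumps(results, indent=2))
            raise PipelineError(f"analyze:{name}", exc) from exc
        results["groups"][name] = result

        pd.DataFrame(
            {
                "contrast": result["contrast_levels"],
                "response_proportion": result["response_proportions"],
                "n": result["n_per_level"],
            }
        ).to_csv(out_dir / f"{name.replace(':', '_')}_contrast_response.csv", index=False)
        if config.make_figures:
            try:
                _figure(key, result, kept, window, out_dir / f"{name.replace(':', '_')}.png")
            except Exception as exc:
                raise PipelineError(f"figure:{name}", exc) from exc

    (out_dir / "results.json").write_text(json.dumps(results, indent=2))
    return results
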