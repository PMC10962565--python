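"""Session, config, and result I/O.

Sessions travel as plain CSV with header ``t,x,y,heading,spikes`` (heading
optional, radians; positions in arena units with the bin size recorded in a
sidecar YAML config).  Fitted results round-trip through a versioned
compressed ``.npz`` container holding the variational state, the spectral
prior, and the hyperparameters.
"""

from __future__ import annotations

import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import PriorSpec, VariationalState
from .kernels import Hyperparams
from .session import Session
from .spectral import SpectralPrior

RESULTS_FORMAT = "lgcpmap-results-1"


def save_session(session: Session, path: str | Path) -> None:
    """Write a session as CSV ``t,x,y[,heading],spikes``."""
    cols = {"t": session.times, "x": session.positions[:, 0],
            "y": session.positions[:, 1]}
    if session.heading is not None:
        cols["heading"] = session.heading
    cols["spikes"] = session.spikes
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def load_session(path: str | Path) -> Session:
    """Read a session CSV; validates the header and monotone uniform times."""
    df = pd.read_csv(path)
    required = {"t", "x", "y", "spikes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"session file {path} missing columns: {sorted(missing)}")
    if df["t"].isna().any():
        bad = int(df["t"].isna().idxmax())
        raise ValueError(f"NaN time at row {bad}")
    heading = df["heading"].to_numpy() if "heading" in df.columns else None
    return Session(times=df["t"].to_numpy(),
                   positions=df[["x", "y"]].to_numpy(),
                   spikes=df["spikes"].to_numpy(),
                   heading=heading)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def save_results(state: VariationalState, prior: PriorSpec, path: str | Path,
                 seed: int | None = None) -> None:
    """Lossless round-trip of VariationalState + PriorSpec (+ hyperparams)."""
    h = prior.hyper
    np.savez_compressed(
        path,
        format=RESULTS_FORMAT,
        mean_coeff=state.mean_coeff,
        marginal_var=state.marginal_var,
        q=state.q,
        expected_rate=state.expected_rate,
        elbo=state.elbo,
        chol=state.chol if state.chol is not None else np.zeros((0, 0)),
        converged=state.converged,
        n_outer=state.n_outer,
        xi=prior.spectral.xi,
        keep=prior.spectral.keep,
        prior_mean=prior.prior_mean,
        pad=prior.pad,
        hyper=np.array([h.period, h.variance_scale, h.dc_offset,
                        np.nan if h.orientation is None else h.orientation])
        if h is not None else np.zeros(0),
        seed=-1 if seed is None else seed,
    )


def load_results(path: str | Path) -> tuple[VariationalState, PriorSpec]:
    try:
        with np.load(path, allow_pickle=False) as z:
            if "format" not in z or str(z["format"]) != RESULTS_FORMAT:
                raise ValueError(f"unrecognized results format in {path}")
            xi = z["xi"]
            keep = z["keep"]
            spectral = SpectralPrior(xi=xi, keep=keep, xi_kept=xi.ravel()[keep])
            hyper = None
            if z["hyper"].size:
                p, s2, c, th = z["hyper"]
                hyper = Hyperparams(period=float(p), variance_scale=float(s2),
                                    dc_offset=float(c),
                                    orientation=None if np.isnan(th) else float(th))
            prior = PriorSpec(spectral=spectral, prior_mean=z["prior_mean"],
                              pad=int(z["pad"]), hyper=hyper)
            chol = z["chol"]
            state = VariationalState(
                mean_coeff=z["mean_coeff"], marginal_var=z["marginal_var"],
                q=z["q"], expected_rate=z["expected_rate"],
                elbo=float(z["elbo"]),
                chol=None if chol.size == 0 else chol,
                converged=bool(z["converged"]), n_outer=int(z["n_outer"]))
            return state, prior
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        raise ValueError(f"could not load results from {path}: {exc}") from exc
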