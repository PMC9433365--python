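"""Trial-table and parameter-file readers and writers.

Trial tables are long (tidy) CSV/TSV files: one row per person x trial with
columns person_id, trial, gain, loss, n_loss, y, censored plus covariates.
Model parameters round-trip through JSON on the natural scale; parameter
files written in the transformed convention (alpha_tilde / tau / sigma /
log_delta) are accepted and converted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import ModelParams, ParamSpace, untransform
from .outcome import InflationSpec

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trials",
    "write_trials",
    "validate_trials",
    "read_params",
    "write_params",
]

REQUIRED_COLUMNS = ("person_id", "trial", "gain", "loss", "n_loss", "y", "censored")


class TrialTableError(ValueError):
    """A trial table violates the format contract."""


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def validate_trials(table: pd.DataFrame, n_cards: int = 32) -> pd.DataFrame:
    """Check the trial-table invariants; offending rows are reported by
    0-based row number (first ten shown)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {', '.join(missing)}")

    def complain(mask: np.ndarray, what: str) -> None:
        if mask.any():
            rows = np.nonzero(mask)[0][:10].tolist()
            raise TrialTableError(f"{what} (rows {rows})")

    y = table["y"].to_numpy()
    c = table["censored"].to_numpy()
    complain((y < 0) | (y > n_cards), f"y outside [0, {n_cards}]")
    complain((c != 0) & (c != 1), "censored must be 0 or 1")
    complain((c == 1) & (y < 1), "censored trials require y >= 1")
    complain(
        (table["n_loss"].to_numpy() < 0) | (table["n_loss"].to_numpy() > n_cards),
        "n_loss outside the deck",
    )
    complain(
        (table["gain"].to_numpy() < 0) | (table["loss"].to_numpy() < 0),
        "gain and loss must be nonnegative",
    )
    dup = table.duplicated(subset=["person_id", "trial"]).to_numpy()
    complain(dup, "duplicate (person_id, trial) pairs")
    return table


def read_trials(path, n_cards: int = 32) -> pd.DataFrame:
    """Read and validate a long-format trial table (CSV or TSV)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep(path))
    try:
        return validate_trials(table, n_cards=n_cards)
    except TrialTableError as exc:
        raise TrialTableError(f"{path}: {exc}") from None


def write_trials(table: pd.DataFrame, path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep(path), index=False)


def write_params(params: ModelParams, path, scalers: dict | None = None) -> None:
    """Serialize model parameters (and optional z-score scalers) as JSON."""
    payload = {
        "alpha": params.alpha.tolist(),
        "beta": params.beta.tolist(),
        "delta": params.delta,
        "phi": params.phi.tolist(),
        "pi": params.pi.tolist(),
        "inflation": {
            "attract_set": list(params.inflation.attract_set),
            "zero": params.inflation.zero,
            "top": params.inflation.top,
            "cap": params.inflation.cap,
        },
    }
    if params.beta_seg is not None:
        payload["beta_seg"] = params.beta_seg.tolist()
    if scalers:
        payload["scalers"] = {k: list(v) for k, v in scalers.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path) -> ModelParams:
    """Read a parameter JSON file (natural or transformed convention)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}") from None

    infl = payload.get("inflation", {})
    inflation = InflationSpec(
        attract_set=tuple(infl.get("attract_set", (4, 8, 10, 12, 16, 20, 24))),
        zero=infl.get("zero", 0),
        top=infl.get("top", 31),
        cap=infl.get("cap", 32),
    )

    if "alpha_tilde" in payload:  # transformed convention
        alpha_tilde = np.asarray(payload["alpha_tilde"], dtype=float)
        beta = np.asarray(payload.get("beta", []), dtype=float)
        S = len(alpha_tilde)
        sigma = np.asarray(payload.get("sigma", [0.0] * (S - 1)), dtype=float)
        log_delta = payload.get(
            "log_delta", np.log(payload.get("delta", 1.0))
        )
        vec = np.concatenate(
            [alpha_tilde, beta, [log_delta], payload["tau"], sigma]
        )
        return untransform(
            vec, ParamSpace(n_segments=S, n_common=len(beta)), inflation
        )

    for key, tol in (("phi", 1e-8), ("pi", 1e-8)):
        w = np.asarray(payload[key], dtype=float)
        if abs(w.sum() - 1.0) > tol:
            raise ValueError(f"{path}: {key} must sum to 1 within {tol}")
    return ModelParams(
        alpha=np.asarray(payload["alpha"], dtype=float),
        beta=np.asarray(payload.get("beta", []), dtype=float),
        delta=float(payload["delta"]),
        phi=np.asarray(payload["phi"], dtype=float),
        pi=np.asarray(payload["pi"], dtype=float),
        beta_seg=(
            np.asarray(payload["beta_seg"], dtype=float)
            if "beta_seg" in payload
            else None
        ),
        inflation=inflation,
    )
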