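"""Convergence diagnostics for multi-chain traces.

Two classical checks: the Gelman-Rubin potential scale reduction factor
(between- vs within-chain variance of the retained draws) and Geweke's
two-window mean-comparison z score, with standard errors from a batch-means
estimate of the spectral density at frequency zero.  Conventional pass
thresholds (R-hat < 1.1, |z| < 2) are configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mcmc import Trace

__all__ = ["gelman_rubin", "geweke", "assess_convergence", "DiagnosticsReport"]


def _psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor for (m, n) chain draws."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    within = float(chains.var(axis=1, ddof=1).mean())
    between_over_n = float(means.var(ddof=1))  # B/n
    if within == 0.0:
        return 1.0 if between_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * within + between_over_n
    # floor at 1: the finite-sample deflation can push var_plus slightly
    # below W when chains agree; report no shrinkage below unity
    return float(np.sqrt(max(var_plus, within) / within))


def gelman_rubin(trace: Trace, params: tuple[str, ...] | None = None) -> dict[str, float]:
    """Per-parameter R-hat from the retained draws of all chains.

    Requires at least two chains and ten retained draws per chain; identical
    chains give exactly 1.
    """
    if trace.n_chains < 2:
        raise ValueError(
            "Gelman-Rubin needs >= 2 chains; rerun the sampler with n_chains >= 2"
        )
    if trace.n_retained < 10:
        raise ValueError("Gelman-Rubin needs >= 10 retained draws per chain")
    names = params if params is not None else trace.param_names
    return {nm: _psrf(trace.draws[:, :, trace.index_of(nm)]) for nm in names}


def _batch_means_se(x: np.ndarray) -> float:
    """Standard error of the mean of x via batch means (batch size ~ sqrt(n)).

    Robust to the autocorrelation of MCMC output; degenerate (constant)
    windows give 0.
    """
    n = x.size
    b = max(1, int(np.sqrt(n)))
    k = n // b
    if k < 2:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    bm = x[: k * b].reshape(k, b).mean(axis=1)
    return float(np.sqrt(bm.var(ddof=1) / k))


def geweke(trace: Trace, first_frac: float = 0.1, last_frac: float = 0.5,
           params: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
    """Per-parameter, per-chain Geweke z comparing early and late window means.

    z = (mean_first - mean_last) / sqrt(se1^2 + se2^2) with spectral standard
    errors from batch means.  Defaults compare the first 10% of each chain
    with its last 50%.  A constant chain yields z = 0 with a warning.
    """
    if first_frac <= 0 or last_frac <= 0 or first_frac + last_frac > 1:
        raise ValueError("windows overlap: need first_frac + last_frac <= 1 (both > 0)")
    n = trace.n_retained
    n1 = int(np.floor(first_frac * n))
    n2 = int(np.floor(last_frac * n))
    if n1 < 10 or n2 < 10:
        raise ValueError("chain too short: both Geweke windows need >= 10 draws")
    names = params if params is not None else trace.param_names
    out: dict[str, np.ndarray] = {}
    for nm in names:
        j = trace.index_of(nm)
        zs = np.empty(trace.n_chains)
        for c in range(trace.n_chains):
            x = trace.draws[c, :, j]
            a, b = x[:n1], x[n - n2:]
            denom = np.hypot(_batch_means_se(a), _batch_means_se(b))
            if denom == 0.0:
                warnings.warn(
                    f"degenerate (constant) draws for {nm!r} in chain {c}; Geweke z set to 0",
                    stacklevel=2,
                )
                zs[c] = 0.0
            else:
                zs[c] = (a.mean() - b.mean()) / denom
        out[nm] = zs
    return out


@dataclass
class DiagnosticsReport:
    """Convergence verdict: R-hat and Geweke z per parameter with pass flags."""

    rhat: dict[str, float]
    geweke_z: dict[str, np.ndarray]
    rhat_threshold: float = 1.1
    geweke_threshold: float = 2.0
    failed_rhat: list[str] = field(default_factory=list)
    failed_geweke: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_rhat and not self.failed_geweke

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "geweke_z": {k: list(v) for k, v in self.geweke_z.items()},
            "thresholds": {"rhat": self.rhat_threshold, "geweke": self.geweke_threshold},
            "failed_rhat": self.failed_rhat,
            "failed_geweke": self.failed_geweke,
            "passed": self.passed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def assess_convergence(trace: Trace, rhat_threshold: float = 1.1,
                       geweke_threshold: float = 2.0) -> DiagnosticsReport:
    """Run both diagnostics against configurable thresholds."""
    rhat = gelman_rubin(trace)
    gz = geweke(trace)
    failed_rhat = sorted(nm for nm, v in rhat.items() if not v < rhat_threshold)
    failed_geweke = sorted(
        nm for nm, z in gz.items() if np.any(np.abs(z) >= geweke_threshold)
    )
    return DiagnosticsReport(
        rhat=rhat,
        geweke_z=gz,
        rhat_threshold=rhat_threshold,
        geweke_threshold=geweke_threshold,
        failed_rhat=failed_rhat,
        failed_geweke=failed_geweke,
    )


def plot_trace_overlay(trace: Trace, params: tuple[str, ...], path: str | Path) -> None:
    """Save per-chain trace overlays for a handful of parameters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(params), 1, figsize=(8, 2.2 * len(params)), squeeze=False)
    for ax, nm in zip(axes[:, 0], params):
        j = trace.index_of(nm)
        for c in range(trace.n_chains):
            ax.plot(trace.draws[c, :, j], lw=0.5, alpha=0.8, label=f"chain {c}")
        ax.set_ylabel(nm)
    axes[0, 0].legend(loc="upper right", fontsize=7)
    axes[-1, 0].set_xlabel("retained draw")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
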