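"""Chain configuration and the retained-draw container."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..bspline import KnotSet

__all__ = ["ChainConfig", "SplineDraw", "PosteriorDraws"]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings.

    ``move_probs`` are the (birth, death, move) proposal probabilities of
    the reversible-jump knot step; at zero knots the death mass is folded
    into birth.  Latent random-walk proposal sds start at the given values
    and adapt toward a 20-40% acceptance rate during burn-in only.
    """

    n_chains: int = 3
    n_iterations: int = 12000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0
    proposal_sd_ee: float = 60.0
    proposal_sd_es: float = 25.0
    move_probs: tuple = (0.35, 0.35, 0.30)
    spline_thin: int = 10
    latent_thin: int = 50
    adapt_interval: int = 100
    k_max: int = 30

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be at least 1")
        if abs(sum(self.move_probs) - 1.0) > 1e-12:
            raise ValueError("move probabilities must sum to 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class SplineDraw:
    """One retained spline state: knot vector, coefficients, covariate slopes.

    ``x_lo``/``x_hi`` record the latent range at that draw, which bounds
    the region where the spline is identified (used by calibration).
    """

    knots: KnotSet
    beta: np.ndarray
    gamma: np.ndarray
    x_lo: float
    x_hi: float


class PosteriorDraws:
    """Retained MCMC draws of every model parameter, per chain.

    Scalar and vector parameters live in ``params`` as arrays of shape
    (n_chains, n_kept) or (n_chains, n_kept, dim).  Spline states and
    latent draws are kept at a coarser thinning (they are bulky), under
    ``splines[attr]`` and ``latents``.
    """

    def __init__(self, model: str, config: ChainConfig):
        self.model = model
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.splines: dict[str, list] = {"ee": [], "es": []}
        self.latents: np.ndarray | None = None  # (chains, kept, n, 2)
        self.acceptance: dict[str, float] = {}

    # -- access ------------------------------------------------------------

    @property
    def n_chains(self) -> int:
        return self.config.n_chains

    def parameter_names(self):
        return sorted(self.params)

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains, shape (n_chains * n_kept[, dim])."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def spline_draws(self, attribute: str) -> list:
        """All retained spline states for one attribute, pooled across chains."""
        return [d for chain in self.splines[attribute] for d in chain]

    def posterior_mean(self, name: str):
        return self.stacked(name).mean(axis=0)

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            cols = {}
            for name in self.parameter_names():
                arr = self.params[name][c]
                if arr.ndim == 1:
                    cols[name] = arr
                else:
                    for d in range(arr.shape[1]):
                        cols[f"{name}_{d + 1}"] = arr[:, d]
            pd.DataFrame(cols).to_csv(path / f"params_chain{c + 1}.csv", index=False)
        for attr in ("ee", "es"):
            if not self.splines[attr]:
                continue
            for c, chain in enumerate(self.splines[attr]):
                with open(path / f"splines_{attr}_chain{c + 1}.jsonl", "w") as fh:
                    for d in chain:
                        fh.write(
                            json.dumps(
                                {
                                    "interior": d.knots.interior.tolist(),
                                    "lower": d.knots.lower,
                                    "upper": d.knots.upper,
                                    "beta": d.beta.tolist(),
                                    "gamma": d.gamma.tolist(),
                                    "x_lo": d.x_lo,
                                    "x_hi": d.x_hi,
                                }
                            )
                            + "\n"
                        )
        meta = {
            "model": self.model,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "acceptance": self.acceptance,
        }
        (path / "manifest.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = Path(path)
        meta = json.loads((path / "manifest.json").read_text())
        raw = dict(meta["config"])
        raw["move_probs"] = tuple(raw["move_probs"])
        config = ChainConfig(**raw)
        out = cls(meta["model"], config)
        out.acceptance = meta.get("acceptance", {})
        frames = [
            pd.read_csv(path / f"params_chain{c + 1}.csv")
            for c in range(config.n_chains)
        ]
        vector_roots: dict[str, int] = {}
        for col in frames[0].columns:
            root, _, idx = col.rpartition("_")
            if root and idx.isdigit():
                vector_roots[root] = max(vector_roots.get(root, 0), int(idx))
        consumed = set()
        for root, dim in vector_roots.items():
            names = [f"{root}_{d + 1}" for d in range(dim)]
            if all(n in frames[0].columns for n in names):
                out.params[root] = np.stack(
                    [f[names].to_numpy() for f in frames], axis=0
                )
                consumed.update(names)
        for col in frames[0].columns:
            if col in consumed:
                continue
            out.params[col] = np.stack([f[col].to_numpy() for f in frames], axis=0)
        for attr in ("ee", "es"):
            chains = []
            for c in range(config.n_chains):
                f = path / f"splines_{attr}_chain{c + 1}.jsonl"
                if not f.exists():
                    break
                chain = []
                for line in f.read_text().splitlines():
                    rec = json.loads(line)
                    chain.append(
                        SplineDraw(
                            knots=KnotSet(
                                np.asarray(rec["interior"]), rec["lower"], rec["upper"]
                            ),
                            beta=np.asarray(rec["beta"]),
                            gamma=np.asarray(rec["gamma"]),
                            x_lo=rec["x_lo"],
                            x_hi=rec["x_hi"],
                        )
                    )
                chains.append(chain)
            out.splines[attr] = chains
        return out
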