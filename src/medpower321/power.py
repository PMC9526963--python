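"""Monte Carlo power estimation for 3-2-1 mediation designs.

For one design: draw ``reps`` datasets from the implied generating model, fit
the chosen estimator (MVM or MSEM), apply the Sobel test to the indirect
effect, and report rejection proportions for 2- and 1-sided decisions, with
non-converged replications excluded from the denominator (completion
accounting).  Grid sweeps run this over every design of a fully crossed grid
with optional checkpointing and process parallelism.

Reproducibility: every source of randomness derives from a single run seed
through counter-based ``SeedSequence`` streams keyed by (seed, design, stream,
counter), so results are identical regardless of execution order or worker
count.  Replications are simulated in fixed-size chunks (chunk size a
deterministic function of the design dimensions only).

The inner simulation samples per-cluster sufficient statistics directly
(see :mod:`medpower321.simulate`); all estimators are functions of these
statistics, so power estimates are distributionally identical to simulating
full datasets.  Set ``use_full_data=True`` to force the full-data path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, GridDefinition, enumerate_grid, SPEC_FIELDS
from .inference import one_sided_from_two, sobel_z_batched
from .msem import fit_msem_batched
from .mvm import fit_mvm_batched
from .population import derive_components
from .simulate import SufficientStats, generate, generate_sufficient

__all__ = [
    "PowerEstimate",
    "run_design",
    "run_grid",
    "estimates_to_frame",
    "summarize_marginals",
    "minimum_samples",
]

ADEQUACY_THRESHOLD = 0.8   # conventional "adequate power" cutoff
ESTIMATORS = ("mvm", "msem")

# per-design stream tags
_STREAM_DATA = 0
_STREAM_BOOT = 1


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection proportions for one design under one estimator."""

    design: DesignSpec
    estimator_tag: str
    reps_requested: int
    reps_completed: int
    rejections_two: int
    rejections_one: int
    seed: int
    alpha: float
    direction: int

    @property
    def power_two(self) -> float:
        return self.rejections_two / self.reps_completed

    @property
    def power_one(self) -> float:
        return self.rejections_one / self.reps_completed

    @property
    def completion_rate(self) -> float:
        return self.reps_completed / self.reps_requested

    @property
    def mc_se(self) -> float:
        """Binomial Monte Carlo standard error of the 2-sided power."""
        p = self.power_two
        return float(np.sqrt(p * (1 - p) / self.reps_completed))


def _data_stream(seed: int, key: int, chunk: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=[int(seed), int(key), _STREAM_DATA, int(chunk)])


def _boot_seed(seed: int, key: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=[int(seed), int(key), _STREAM_BOOT, int(rep)])


def _chunk_size(n3: int, n2: int) -> int:
    # bound peak memory to a few tens of MB of unit-level arrays
    return max(1, int(2_000_000 // max(n3 * n2, 1)))


def run_design(
    spec: DesignSpec,
    estimator: str = "mvm",
    reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    direction: int = 1,
    bootstrap_reps: int = 200,
    se_method: str = "robust",
    use_full_data: bool = False,
) -> PowerEstimate:
    """Estimate power for one design by Monte Carlo replication.

    Raises ``RuntimeError`` if every replication fails to converge.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    params = derive_components(spec)
    n3, n2, n1 = spec.dims
    key = spec.key()

    chunk = _chunk_size(n3, n2)
    completed = 0
    rej_two = 0
    rej_one = 0
    done = 0
    ci = 0
    while done < reps:
        r = min(chunk, reps - done)
        ss = _data_stream(seed, key, ci)
        if use_full_data:
            rng = np.random.default_rng(ss)
            stats = [
                SufficientStats.from_dataset(generate(params, n3, n2, n1, rng))
                for _ in range(r)
            ]
            st = SufficientStats(
                x=np.stack([s.x for s in stats]),
                m_bar=np.stack([s.m_bar for s in stats]),
                y_bar=np.stack([s.y_bar for s in stats]),
                s_mm=np.stack([s.s_mm for s in stats]),
                s_my=np.stack([s.s_my for s in stats]),
                s_yy=np.stack([s.s_yy for s in stats]),
                ss1=np.stack([s.ss1 for s in stats]),
                n2=n2, n1=n1,
            )
        else:
            st = generate_sufficient(params, n3, n2, n1, ss, reps=r)

        if estimator == "mvm":
            fit = fit_mvm_batched(st, se_method=se_method)
        else:
            seeds = [_boot_seed(seed, key, done + j) for j in range(r)]
            fit = fit_msem_batched(st, bootstrap_reps, seeds)

        z = sobel_z_batched(fit["a_hat"], fit["se_a"], fit["b3_hat"], fit["se_b3"])
        good = np.asarray(fit["converged"]) & np.isfinite(z)
        zg = z[good]
        completed += int(good.sum())
        rej_two += int((np.abs(zg) >= _crit_two(alpha)).sum())
        rej_one += int(one_sided_from_two(zg, direction, alpha).sum())
        done += r
        ci += 1

    if completed == 0:
        raise RuntimeError(f"degenerate design: no replication converged for {spec}")
    return PowerEstimate(
        design=spec,
        estimator_tag=estimator.upper(),
        reps_requested=reps,
        reps_completed=completed,
        rejections_two=rej_two,
        rejections_one=rej_one,
        seed=seed,
        alpha=alpha,
        direction=direction,
    )


def _crit_two(alpha: float) -> float:
    from scipy import stats as sps
    return float(sps.norm.isf(alpha / 2))


def estimates_to_frame(estimates: Iterable[PowerEstimate]) -> pd.DataFrame:
    """Tabulate estimates: design fields + power columns, one row per design."""
    rows = []
    for e in estimates:
        row = e.design.to_dict()
        row.update(
            total_sample=e.design.n3 * e.design.n2 * e.design.n1,
            estimator=e.estimator_tag,
            reps_requested=e.reps_requested,
            reps_completed=e.reps_completed,
            rejections_two=e.rejections_two,
            rejections_one=e.rejections_one,
            power_two=e.power_two,
            power_one=e.power_one,
            mc_se=e.mc_se,
            seed=e.seed,
            alpha=e.alpha,
            direction=e.direction,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _run_one(spec_dict, estimator, reps, seed, alpha, direction, bootstrap_reps,
             se_method):
    spec = DesignSpec(**spec_dict)
    return run_design(spec, estimator, reps, seed, alpha, direction,
                      bootstrap_reps, se_method)


def run_grid(
    grid: GridDefinition | Sequence[DesignSpec] | None = None,
    estimator: str = "mvm",
    reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    direction: int = 1,
    bootstrap_reps: int = 200,
    se_method: str = "robust",
    workers: int = 1,
    checkpoint: str | os.PathLike | None = None,
    checkpoint_every: int = 200,
    progress: bool = False,
) -> list[PowerEstimate]:
    """Power for every design of a grid, with checkpoint/resume.

    The checkpoint is a CSV of completed rows keyed by the design's stable
    key; resuming with the same (seed, reps, estimator, alpha, direction)
    skips completed designs and yields results identical to a fresh run.
    A checkpoint written under different run settings raises ``ValueError``.
    """
    if grid is None or isinstance(grid, GridDefinition):
        specs = list(enumerate_grid(grid))
    else:
        specs = list(grid)

    run_cfg = dict(estimator=estimator.upper(), reps_requested=reps, seed=seed,
                   alpha=alpha, direction=direction)
    done: dict[int, PowerEstimate] = {}
    if checkpoint is not None and os.path.exists(checkpoint):
        prev = pd.read_csv(checkpoint)
        for col, want in run_cfg.items():
            vals = prev[col].unique()
            if len(vals) and not np.all(vals == want):
                raise ValueError(
                    f"checkpoint {checkpoint} was written with {col}={vals}, "
                    f"current run uses {want}")
        for _, row in prev.iterrows():
            vals = {f: (int(row[f]) if f in ("n3", "n2", "n1") else float(row[f]))
                    for f in SPEC_FIELDS}
            spec = DesignSpec(**vals)
            done[spec.key()] = PowerEstimate(
                design=spec, estimator_tag=row["estimator"],
                reps_requested=int(row["reps_requested"]),
                reps_completed=int(row["reps_completed"]),
                rejections_two=int(row["rejections_two"]),
                rejections_one=int(row["rejections_one"]),
                seed=int(row["seed"]), alpha=float(row["alpha"]),
                direction=int(row["direction"]),
            )

    todo = [s for s in specs if s.key() not in done]
    results = dict(done)

    def flush(batch):
        if checkpoint is None or not batch:
            return
        df = estimates_to_frame(batch)
        header = not os.path.exists(checkpoint)
        df.to_csv(checkpoint, mode="a", header=header, index=False)

    if workers > 1 and todo:
        from joblib import Parallel, delayed
        pending = (
            delayed(_run_one)(s.to_dict(), estimator, reps, seed, alpha,
                              direction, bootstrap_reps, se_method)
            for s in todo
        )
        batch = []
        for e in Parallel(n_jobs=workers, return_as="generator")(pending):
            results[e.design.key()] = e
            batch.append(e)
            if len(batch) >= checkpoint_every:
                flush(batch)
                batch = []
        flush(batch)
    else:
        batch = []
        it = enumerate(todo)
        for i, s in it:
            e = run_design(s, estimator, reps, seed, alpha, direction,
                           bootstrap_reps, se_method)
            results[s.key()] = e
            batch.append(e)
            if len(batch) >= checkpoint_every:
                flush(batch)
                batch = []
            if progress and (i + 1) % 500 == 0:
                print(f"  {i + 1}/{len(todo)} designs done", flush=True)
        flush(batch)

    return [results[s.key()] for s in specs]


# ---------------------------------------------------------------------------
# Summaries


def summarize_marginals(
    estimates: Iterable[PowerEstimate] | pd.DataFrame,
    threshold: float = ADEQUACY_THRESHOLD,
    power_col: str = "power_two",
) -> pd.DataFrame:
    """Adequately powered design counts by study characteristic.

    One row per (characteristic, value): total designs, number with power >=
    ``threshold``, and the proportion — the layout of a design-census table,
    with the total-sample-size breakdown appended.
    """
    df = estimates if isinstance(estimates, pd.DataFrame) else estimates_to_frame(estimates)
    adequate = df[power_col] >= threshold
    rows = [{
        "characteristic": "total", "value": "",
        "n_designs": len(df), "n_adequate": int(adequate.sum()),
        "proportion": float(adequate.mean()),
    }]
    for char in list(SPEC_FIELDS) + ["total_sample"]:
        if df[char].nunique() == 1 and char == "b2":
            continue
        for val, sub in df.groupby(char, sort=True):
            ok = sub[power_col] >= threshold
            rows.append({
                "characteristic": char, "value": val,
                "n_designs": len(sub), "n_adequate": int(ok.sum()),
                "proportion": float(ok.mean()),
            })
    return pd.DataFrame(rows)


def minimum_samples(
    estimates: Iterable[PowerEstimate] | pd.DataFrame,
    threshold: float = ADEQUACY_THRESHOLD,
    power_col: str = "power_two",
    cell_keys: Sequence[str] = ("icc_m3", "icc_y3", "a3", "b3", "c3p"),
) -> pd.DataFrame:
    """Smallest adequate (n3, n2, n1) per design cell, or none.

    Within each cell (default: ICCs of M and Y at level 3, the two indirect
    paths, and the direct effect), the minimum is lexicographic — smallest
    n3, then n2, then n1 — among sample-size combinations whose power meets
    ``threshold``; cells with no adequate combination get missing sizes.
    Fields not in ``cell_keys`` (e.g. icc_y2) are marginalized: a combination
    qualifies if any of its designs in the cell is adequate.
    """
    df = estimates if isinstance(estimates, pd.DataFrame) else estimates_to_frame(estimates)
    out = []
    for cell, sub in df.groupby(list(cell_keys), sort=True):
        ok = sub[sub[power_col] >= threshold]
        row = dict(zip(cell_keys, cell if isinstance(cell, tuple) else (cell,)))
        if len(ok):
            best = ok.sort_values(["n3", "n2", "n1"], kind="mergesort").iloc[0]
            row.update(n3=int(best.n3), n2=int(best.n2), n1=int(best.n1),
                       power=float(best[power_col]))
        else:
            row.update(n3=pd.NA, n2=pd.NA, n1=pd.NA, power=np.nan)
        out.append(row)
    return pd.DataFrame(out)
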