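"""Study orchestration: parameter sweeps, metric tables, and comparisons.

A study sweeps the inhibitory firing threshold ``Vd2`` and the global
coupling gain ``S`` over a grid, runs each model several times with
independent seeds, and computes the symbolic-dynamics readouts for each
(pass-band, tau) condition.  The focus comparisons follow the study design:
a balanced model (Vd2 7.0, S 1.0) against a low-E-I model (Vd2 6.5) and a
high-E-I model (Vd2 7.5), analysed at whole-brain level (t-tests, effect
sizes), regional level (Mann-Whitney with two-stage FDR), and through the
hub disruption index.

Seeding: each (Vd2, S, run) cell draws its simulation seed from a
``numpy.random.SeedSequence`` spawned from the base seed and the cell's
grid indices, so any single cell can be recomputed in isolation and the
whole study is bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import StructuralConnectome
from .neural_mass import ModelParameters, ei_ratio_curve, simulate
from .network_stats import (
    HDIResult,
    RegionalProfile,
    fdr_bky,
    functional_degree,
    hub_disruption_index,
    independent_t_test,
    mann_whitney_u,
    pearson_r,
)
from .symbolic import (
    SymbolizationParams,
    _pairwise_measures,
    _symbolize_symbols,
    bandpass,
)

__all__ = ["StudyConfig", "StudyResult", "run_study",
           "summarize_whole_brain", "compare_focus_models",
           "correlate_with_vd2"]

#: the three (band, tau) analysis conditions of the study
DEFAULT_CONDITIONS = (
    ((0.5, 70.0), 1),
    ((6.0, 13.0), 1),
    ((0.5, 70.0), 50),
)


def _condition_label(band: tuple[float, float], tau: int) -> str:
    return f"{band[0]:g}-{band[1]:g}Hz_tau{tau}"


@dataclass(frozen=True)
class StudyConfig:
    """Sweep grids, run protocol, and analysis conditions of one study."""

    vd2_grid: tuple[float, ...] = (6.0, 6.5, 7.0, 7.5, 8.0)
    s_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    runs_per_model: int = 10
    samples_per_run: int = 4096
    conditions: tuple[tuple[tuple[float, float], int], ...] = DEFAULT_CONDITIONS
    base_seed: int = 0
    embedding_n: int = 4
    burn_in: int = 1000
    params: ModelParameters = field(default_factory=ModelParameters)

    def __post_init__(self):
        if not self.vd2_grid or not self.s_grid:
            raise ValueError("parameter grids must be nonempty")
        if self.runs_per_model < 1:
            raise ValueError("runs_per_model must be >= 1")
        max_tau = max(tau for _, tau in self.conditions)
        if self.samples_per_run < (self.embedding_n - 1) * max_tau + 1:
            raise ValueError("samples_per_run too short for the largest tau")

    def cell_seed(self, vd2_idx: int, s_idx: int, run: int) -> int:
        ss = np.random.SeedSequence(
            entropy=self.base_seed, spawn_key=(vd2_idx, s_idx, run)
        )
        return int(ss.generate_state(1)[0])


@dataclass
class StudyResult:
    """All study tables, tidy and traceable to (model, run, condition).

    ``matrices`` maps (vd2, s, condition_label, measure) to the 78x78
    connectivity matrix averaged across runs.
    """

    config: StudyConfig
    connectome: StructuralConnectome
    ei_table: pd.DataFrame          # vd2, s, run, seed, e_mean, i_mean, ei_ratio
    whole_brain: pd.DataFrame       # vd2, s, condition, run, pe, wsmi, jpe_inv
    regional_pe: pd.DataFrame       # vd2, s, condition, run, region, pe
    regional_degree: pd.DataFrame   # + measure, degree
    matrices: dict

    def ei_curve(self, s: float) -> pd.DataFrame:
        """Normalised rate and E-I ratio curve along the Vd2 grid at gain s.

        Whole-brain mean rates are averaged over runs per model, min-max
        normalised across the Vd2 sweep, and combined as E/(E+I).
        """
        sub = self.ei_table[self.ei_table.s == s]
        by_model = sub.groupby("vd2")[["e_mean", "i_mean"]].mean()
        ratios = ei_ratio_curve(
            by_model.e_mean.to_numpy(), by_model.i_mean.to_numpy()
        )
        return pd.DataFrame(
            {
                "vd2": by_model.index.to_numpy(),
                "e_norm": _minmax(by_model.e_mean.to_numpy()),
                "i_norm": _minmax(by_model.i_mean.to_numpy()),
                "ei_ratio": ratios,
            }
        )

    def save(self, out_dir: str | Path) -> None:
        """Write every table (and averaged matrices) as delimited text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ei_table.to_csv(out / "ei_table.tsv", sep="\t", index=False)
        self.whole_brain.to_csv(out / "whole_brain.tsv", sep="\t", index=False)
        self.regional_pe.to_csv(out / "regional_pe.tsv", sep="\t", index=False)
        self.regional_degree.to_csv(
            out / "regional_degree.tsv", sep="\t", index=False
        )
        for (vd2, s, cond, measure), mat in self.matrices.items():
            name = f"matrix_{measure}_vd2-{vd2:g}_s-{s:g}_{cond}.tsv"
            header = f"# measure={measure} vd2={vd2:g} s={s:g} condition={cond}"
            with open(out / name, "w") as fh:
                fh.write(header + "\n")
                np.savetxt(fh, mat, delimiter="\t", fmt="%.10g")


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    return x - x.min() if span == 0 else (x - x.min()) / span


def run_study(
    config: StudyConfig,
    connectome: StructuralConnectome,
    progress: bool = False,
) -> StudyResult:
    """Run the full sweep and compute every per-run readout table."""
    if connectome.n_regions != config.params.N:
        config = replace(
            config, params=replace(config.params, N=connectome.n_regions)
        )
    params0 = config.params
    n_regions = connectome.n_regions
    fs = 1.0 / params0.dt
    labels = connectome.labels
    cond_labels = [
        _condition_label(band, tau) for band, tau in config.conditions
    ]

    ei_rows, wb_rows, pe_rows, deg_rows = [], [], [], []
    matrices: dict = {}
    offdiag = ~np.eye(n_regions, dtype=bool)

    for iv, vd2 in enumerate(config.vd2_grid):
        for is_, s in enumerate(config.s_grid):
            params = replace(params0, Vd2=vd2, S_couple=s)
            # per-condition accumulators of run-level matrices
            acc = {
                (cl, m): np.zeros((n_regions, n_regions))
                for cl in cond_labels
                for m in ("wsmi", "jpe_inv")
            }
            for run in range(config.runs_per_model):
                seed = config.cell_seed(iv, is_, run)
                res = simulate(
                    params,
                    connectome,
                    config.samples_per_run,
                    seed,
                    burn_in=config.burn_in,
                )
                ei_rows.append(
                    dict(
                        vd2=vd2,
                        s=s,
                        run=run,
                        seed=seed,
                        e_mean=float(res.e_rate.mean()),
                        i_mean=float(res.i_rate.mean()),
                        ei_ratio=float(
                            (
                                res.e_rate.mean(axis=1)
                                / (
                                    res.e_rate.mean(axis=1)
                                    + res.i_rate.mean(axis=1)
                                )
                            ).mean()
                        ),
                    )
                )
                for (band, tau), cl in zip(config.conditions, cond_labels):
                    filtered = bandpass(res.eeg, fs, band)
                    symbols = _symbolize_symbols(
                        filtered, config.embedding_n, tau
                    )
                    n_pat = math.factorial(config.embedding_n)
                    length = symbols.shape[1]
                    pe_vals = np.empty(n_regions)
                    for r in range(n_regions):
                        cnt = np.bincount(symbols[r], minlength=n_pat)
                        p = cnt[cnt > 0] / length
                        pe_vals[r] = -(p * np.log(p)).sum() / math.log(n_pat)
                    wsmi_mat, jpe_mat = _pairwise_measures(
                        symbols, config.embedding_n
                    )
                    acc[(cl, "wsmi")] += wsmi_mat
                    acc[(cl, "jpe_inv")] += jpe_mat
                    wb_rows.append(
                        dict(
                            vd2=vd2,
                            s=s,
                            condition=cl,
                            run=run,
                            pe=float(pe_vals.mean()),
                            wsmi=float(wsmi_mat[offdiag].mean()),
                            jpe_inv=float(jpe_mat[offdiag].mean()),
                        )
                    )
                    for r in range(n_regions):
                        pe_rows.append(
                            dict(
                                vd2=vd2,
                                s=s,
                                condition=cl,
                                run=run,
                                region=labels[r],
                                pe=pe_vals[r],
                            )
                        )
                    for measure, mat in (
                        ("wsmi", wsmi_mat),
                        ("jpe_inv", jpe_mat),
                    ):
                        deg = mat.sum(axis=1) / (n_regions - 1)
                        for r in range(n_regions):
                            deg_rows.append(
                                dict(
                                    vd2=vd2,
                                    s=s,
                                    condition=cl,
                                    measure=measure,
                                    run=run,
                                    region=labels[r],
                                    degree=deg[r],
                                )
                            )
            for (cl, m), total in acc.items():
                matrices[(vd2, s, cl, m)] = total / config.runs_per_model
            if progress:
                print(f"model Vd2={vd2:g} S={s:g} done", flush=True)

    return StudyResult(
        config=config,
        connectome=connectome,
        ei_table=pd.DataFrame(ei_rows),
        whole_brain=pd.DataFrame(wb_rows),
        regional_pe=pd.DataFrame(pe_rows),
        regional_degree=pd.DataFrame(deg_rows),
        matrices=matrices,
    )


def summarize_whole_brain(result: StudyResult) -> dict:
    """(measure, condition) -> Vd2 x S table of whole-brain means.

    Each cell averages over regions (or region pairs) and runs; averaging
    order is immaterial because all the summaries are plain means.
    """
    tables = {}
    for measure in ("pe", "wsmi", "jpe_inv"):
        for cond in result.whole_brain.condition.unique():
            sub = result.whole_brain[result.whole_brain.condition == cond]
            tables[(measure, cond)] = sub.pivot_table(
                index="vd2", columns="s", values=measure, aggfunc="mean"
            )
    return tables


def correlate_with_vd2(
    result: StudyResult, s: float = 1.0, level: str = "run"
) -> pd.DataFrame:
    """Pearson correlation of each whole-brain measure with Vd2 at gain s.

    ``level='run'`` treats every run as an observation (n = runs x models);
    ``level='model'`` first averages runs within each model (n = models).
    """
    sub = result.whole_brain[result.whole_brain.s == s]
    rows = []
    for cond in sub.condition.unique():
        cs = sub[sub.condition == cond]
        if level == "model":
            cs = cs.groupby("vd2", as_index=False)[
                ["pe", "wsmi", "jpe_inv"]
            ].mean()
        for measure in ("pe", "wsmi", "jpe_inv"):
            r, p = pearson_r(cs.vd2.to_numpy(), cs[measure].to_numpy())
            rows.append(
                dict(condition=cond, measure=measure, r=r, p=p, n=len(cs))
            )
    return pd.DataFrame(rows)


def compare_focus_models(
    result: StudyResult,
    balanced_vd2: float = 7.0,
    low_vd2: float = 6.5,
    high_vd2: float = 7.5,
    s: float = 1.0,
    fdr_q: float = 0.01,
) -> dict:
    """Whole-brain tests, regional tests, and HDI for the focus models.

    Returns a dict of tidy tables:

    * ``whole_brain_tests`` — independent t-tests with Cohen's d, each
      measure x condition x comparison, run-level observations;
    * ``regional_tests`` — per-region Mann-Whitney U across runs with
      two-stage FDR flags per (measure, condition, comparison) family;
    * ``hdi`` — hub-disruption regressions (2 measures x conditions x 2
      comparisons), x-axis always the balanced-model degree.
    """
    cfg = result.config
    for vd2 in (balanced_vd2, low_vd2, high_vd2):
        if vd2 not in cfg.vd2_grid:
            raise ValueError(f"focus model Vd2={vd2} not in the study grid")
    comparisons = [("low", low_vd2), ("high", high_vd2)]
    conds = list(result.whole_brain.condition.unique())

    wb = result.whole_brain[result.whole_brain.s == s]
    wb_rows = []
    for cond in conds:
        base = wb[(wb.condition == cond) & (wb.vd2 == balanced_vd2)]
        for name, vd2 in comparisons:
            other = wb[(wb.condition == cond) & (wb.vd2 == vd2)]
            for measure in ("pe", "wsmi", "jpe_inv"):
                t, p, d = independent_t_test(
                    other[measure].to_numpy(), base[measure].to_numpy()
                )
                wb_rows.append(
                    dict(
                        comparison=name,
                        vd2=vd2,
                        condition=cond,
                        measure=measure,
                        t=t,
                        p=p,
                        cohens_d=d,
                    )
                )

    # regional Mann-Whitney tests, FDR-corrected within each family
    reg_rows = []
    regions = list(result.connectome.labels)
    for cond in conds:
        for name, vd2 in comparisons:
            families = []
            # PE family
            pe = result.regional_pe[
                (result.regional_pe.s == s)
                & (result.regional_pe.condition == cond)
            ]
            families.append(("pe", pe, "pe"))
            for measure in ("wsmi", "jpe_inv"):
                dd = result.regional_degree[
                    (result.regional_degree.s == s)
                    & (result.regional_degree.condition == cond)
                    & (result.regional_degree.measure == measure)
                ]
                families.append((f"degree_{measure}", dd, "degree"))
            for fam_name, table, value_col in families:
                ps, us = [], []
                for region in regions:
                    a = table[
                        (table.vd2 == vd2) & (table.region == region)
                    ][value_col].to_numpy()
                    b = table[
                        (table.vd2 == balanced_vd2) & (table.region == region)
                    ][value_col].to_numpy()
                    u, p = mann_whitney_u(a, b)
                    us.append(u)
                    ps.append(p)
                flags = fdr_bky(ps, q=fdr_q)
                for region, u, p, flag in zip(regions, us, ps, flags):
                    reg_rows.append(
                        dict(
                            comparison=name,
                            vd2=vd2,
                            condition=cond,
                            family=fam_name,
                            region=region,
                            U=u,
                            p=p,
                            significant=bool(flag),
                        )
                    )

    hdi_rows = []
    for cond in conds:
        for measure in ("wsmi", "jpe_inv"):
            ref_mat = result.matrices[(balanced_vd2, s, cond, measure)]
            ref = functional_degree(ref_mat, labels=tuple(regions))
            for name, vd2 in comparisons:
                pert_mat = result.matrices[(vd2, s, cond, measure)]
                pert = functional_degree(pert_mat, labels=tuple(regions))
                h = hub_disruption_index(ref, pert)
                hdi_rows.append(
                    dict(
                        comparison=name,
                        vd2=vd2,
                        condition=cond,
                        measure=measure,
                        offset=h.offset,
                        slope=h.slope,
                        r_squared=h.r_squared,
                        df_num=h.df_num,
                        df_den=h.df_den,
                        f_stat=h.f_stat,
                        p_value=h.p_value,
                    )
                )

    return {
        "whole_brain_tests": pd.DataFrame(wb_rows),
        "regional_tests": pd.DataFrame(reg_rows),
        "hdi": pd.DataFrame(hdi_rows),
    }
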