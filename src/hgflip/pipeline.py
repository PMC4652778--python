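"""End-to-end driver: simulate -> reweight -> profiles -> pathways -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .fes import R_KCAL, marginal, min_path_profile, slice_profile, wham2d
from .surface import (convergence_report, delta_g, extract_paths, find_minima,
                      label_basins)
from .synthetic import MCParams, make_window_suite, model_surface
from .umbrella import build_window_grid

log = logging.getLogger("hgflip")


def run_pipeline(config=None, surface=None, ensembles=None, write=True):
    """Run the full analysis and return a JSON-serializable report.

    When no ensembles are supplied, the synthetic generator samples the
    (default or given) model surface over the configured window grid; the
    report then also contains the generator's ground truth for comparison.
    """
    config = config or RunConfig()
    grid = build_window_grid(config.n_cpdb, config.cpdb_range,
                             config.n_chi, config.chi_range,
                             config.k_cpdb, config.k_chi)
    report = {"n_windows": len(grid), "temperature": config.temperature}

    truth = None
    if ensembles is None:
        surface = surface or model_surface()
        params = MCParams(temperature=config.temperature,
                          n_steps=config.n_steps, n_equil=config.n_equil,
                          thin=config.thin, seed=config.seed)
        log.info("sampling %d windows (seed=%d, %d samples/window)",
                 len(grid), config.seed, params.n_samples)
        ensembles = make_window_suite(surface, grid, params,
                                      master_seed=config.seed)
    if surface is not None:
        truth = surface

    log.info("reweighting %d ensembles", len(ensembles))
    fes, wham = wham2d(ensembles, temperature=config.temperature,
                       tol=config.wham_tol, max_iter=config.wham_max_iter,
                       bin_width=config.bin_width)
    report["wham"] = {"converged": bool(wham.converged),
                      "iterations": int(wham.iterations),
                      "residual": float(wham.residual)}

    minima = find_minima(fes)
    labels = label_basins(minima,
                          flip_threshold_small=config.flip_small_cutoff)
    by_label = {}
    for lab in labels:
        by_label.setdefault(lab.label, lab)
    report["basins"] = [
        {"label": lab.label, "cpdb": lab.point.cpdb, "chi": lab.point.chi,
         "F": lab.point.F} for lab in labels]

    wc, hg = by_label.get("WC"), by_label.get("HG")
    if wc and hg:
        report["delta_g_wc_to_hg"] = delta_g(fes, wc, hg)
        paths = extract_paths(fes, wc, hg,
                              small_cutoff=config.flip_small_cutoff,
                              large_cutoff=config.flip_large_cutoff)
        report["paths"] = [
            {"class": p.klass,
             "forward_barrier": p.forward_barrier,
             "reverse_barrier": p.reverse_barrier,
             "ts": {"cpdb": p.ts.cpdb, "chi": p.ts.chi, "F": p.ts.F},
             "n_sub_ts": len(p.sub_ts)}
            for p in paths]
    ls = by_label.get("LS")
    report["ls_present"] = ls is not None
    if ls:
        report["ls_location"] = {"cpdb": ls.point.cpdb, "chi": ls.point.chi,
                                 "F": ls.point.F}

    conv = convergence_report(
        ensembles, list(config.convergence_fractions),
        wham_kwargs=dict(temperature=config.temperature,
                         tol=config.wham_tol,
                         max_iter=config.wham_max_iter,
                         bin_width=config.bin_width,
                         cpdb_edges=fes.cpdb_edges,
                         chi_edges=fes.chi_edges))
    report["convergence"] = {"fractions": conv.fractions,
                             "rms_error": conv.rms_error,
                             "kBT": conv.threshold}

    if truth is not None:
        tg = truth.true_grid(fes.cpdb_edges, fes.chi_edges,
                             config.temperature)
        common = fes.sampled_mask
        diff = fes.F[common] - tg.F[common]
        low = tg.F[common] < 12.0
        d = diff[low] - diff[low].mean()
        report["truth"] = {"designed_delta_g": truth.delta_g,
                           "rmse_vs_truth_below_12": float(
                               np.sqrt(np.mean(d ** 2)))}

    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_fes
        write_fes(fes, outdir / "fes.tsv")
        for name, prof in (("marginal_chi", marginal(fes, "chi")),
                           ("marginal_cpdb", marginal(fes, "cpdb")),
                           ("slice_cpdb0", slice_profile(fes, 0.0)),
                           ("minpath_chi", min_path_profile(fes, "chi")),
                           ("minpath_cpdb", min_path_profile(fes, "cpdb"))):
            np.savetxt(outdir / f"{name}.tsv",
                       np.column_stack([prof.centers, prof.F]),
                       header=f"{prof.axis}_center F_kcal_mol")
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        (outdir / "report.txt").write_text(_human_report(report))
        log.info("report written to %s", outdir)
    return report, fes


def _human_report(report):
    lines = [f"windows: {report['n_windows']} at {report['temperature']} K"]
    if "delta_g_wc_to_hg" in report:
        lines.append(
            f"dG(WC->HG) = {report['delta_g_wc_to_hg']:.2f} kcal/mol")
    for p in report.get("paths", []):
        lines.append(
            f"route {p['class']:>2}: forward barrier "
            f"{p['forward_barrier']:.2f} kcal/mol, TS at "
            f"(CPDb={p['ts']['cpdb']:.1f}, chi={p['ts']['chi']:.1f})"
            + (f", {p['n_sub_ts']} sub-TS" if p['n_sub_ts'] > 1 else ""))
    if report.get("ls_present"):
        ls = report["ls_location"]
        lines.append(f"LS intermediate at (CPDb={ls['cpdb']:.1f}, "
                     f"chi={ls['chi']:.1f}), F={ls['F']:.2f} kcal/mol")
    conv = report.get("convergence")
    if conv:
        rms = ", ".join(f"{f:.2f}: {r:.3f}" for f, r in
                        zip(conv["fractions"], conv["rms_error"]))
        lines.append(f"convergence RMS (kcal/mol) per fraction [{rms}] "
                     f"vs kBT = {conv['kBT']:.3f}")
    return "\n".join(lines) + "\n"
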