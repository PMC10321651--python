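"""The experiment matrix: paired chewing/suckling runs, metopic-closure
sweeps, per-muscle decomposition, and material / boundary-condition
sensitivity analyses, with qualitative regression checks.

The four qualitative checks regression-tested on the frozen default
geometry document which behaviors of the patient-based study the
simplified synthetic calvarium reproduces:

* ``sign_schematic`` — chewing and suckling put the metopic and sagittal
  sutures in cross-axial tension and the coronal, lambdoid and squamous
  sutures in compression (sutures with |strain| < 1 microstrain are
  reported as unclassified, mirroring the source schematic's materiality
  convention);
* ``closure_trend`` — metopic cross-axial strain magnitude decreases
  monotonically as the metopic suture closes, while other sutures change
  comparatively little;
* ``profile_minima`` — the patent-model medial-lateral midline profile has
  local minima at the nasion- and fontanelle-adjacent ends of the metopic
  suture;
* ``shear_ranking`` — coronal and squamous cumulative shear exceed metopic
  cumulative shear in patent models.

Failures are reported, never silently adjusted away.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__, analytics, fem, loads
from .geometry import build_calvarium, default_attachments
from .io import PipelineConfig, write_vtk

REGIONS_OF_INTEREST = ("frontal_eminence", "supraorbital", "lateral_orbital", "midface")


@dataclass
class CaseResult:
    name: str
    displacement: np.ndarray
    strain: fem.StrainField
    stress: fem.StressField
    suture_table: pd.DataFrame
    profiles: dict  # component -> MidlineProfile
    regional: pd.DataFrame
    equilibrium: dict
    force_table: pd.DataFrame | None = None


@dataclass
class ResultBundle:
    config: dict
    mesh_hash: str
    mesh: object
    cases: dict  # name -> CaseResult
    provenance: dict = field(default_factory=dict)


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = {
        "specific_tension": config.specific_tension,
        "palatal_pressure_mmHg": config.palatal_pressure_mmHg,
        "bite_point": config.bite_point,
        "foramen_magnum_constrained": config.foramen_magnum_constrained,
        "seed": config.seed,
        "muscles": {k: dict(v) for k, v in config.muscles.items()},
        "materials": {
            r: (m.youngs_modulus, m.poisson_ratio) for r, m in config.materials.items()
        },
        "calvarium": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config.calvarium).items()
        },
    }
    return snap


def _solve_named_case(mesh, attachments, config, solver, name) -> CaseResult:
    case = loads.build_load_case(name, config, mesh, attachments)
    forces, dirichlet = loads.realize_loads(case, mesh)
    dir_resolved = [(mesh.node_sets[s], axes) for s, axes in dirichlet]
    U, info = solver.solve(forces, dir_resolved)
    strain = fem.recover_strain(mesh, U)
    stress = fem.stress_from_strain(strain, mesh, config.materials)
    table = analytics.suture_table(strain, mesh, config.engineering_shear_reporting)
    profiles = {
        "zz": analytics.midsagittal_profile(strain, mesh, "zz"),
        "cumulative_shear": analytics.midsagittal_profile(strain, mesh, "cumulative_shear"),
    }
    regional_rows = []
    for region in REGIONS_OF_INTEREST:
        row = analytics.regional_summary(strain.principal[:, 0] * 1e6, mesh, region)
        row["field"] = "eps1_microstrain"
        regional_rows.append(row)
        row_vm = analytics.regional_summary(stress.von_mises, mesh, region,
                                            thresholds=(0.05, 0.2, 0.5))
        row_vm["field"] = "von_mises_MPa"
        regional_rows.append(row_vm)
    equilibrium = {
        "residual": info["residual"],
        "net_applied": info["applied_total"].tolist(),
        "net_reaction": info["reaction_total"].tolist(),
    }
    return CaseResult(name, U, strain, stress, table, profiles,
                      pd.DataFrame(regional_rows), equilibrium,
                      force_table=loads.force_table(case))


def run_model(config: PipelineConfig, cases=("chewing_R_working", "suckling")) -> ResultBundle:
    """Build the mesh and solve the requested load cases."""
    config.validate()
    mesh = build_calvarium(config.calvarium)
    attachments = default_attachments(mesh)
    solver = fem.CachedSolver(mesh, config.materials)
    out = {}
    for name in cases:
        out[name] = _solve_named_case(mesh, attachments, config, solver, name)
    return ResultBundle(
        config=_config_snapshot(config),
        mesh_hash=mesh.content_hash(),
        mesh=mesh,
        cases=out,
        provenance={"version": __version__, "timestamp": time.strftime("%Y-%m-%d")},
    )


def closure_sweep(config: PipelineConfig, fractions=(0.0, 0.25, 0.5, 0.75)) -> pd.DataFrame:
    """Per-closure-fraction suture summaries for both behaviors.

    The returned frame has one row per (fraction, case, suture) with the
    cross-axial strain and cumulative shear; trend diagnostics are in
    ``closure_trend_diagnostics``.
    """
    rows = []
    for frac in fractions:
        cfg = replace_closure(config, frac)
        bundle = run_model(cfg)
        for case_name, res in bundle.cases.items():
            for _, r in res.suture_table.iterrows():
                rows.append(
                    dict(fraction=frac, case=case_name, suture=r["suture"],
                         cross_axial=r["cross_axial"],
                         cumulative_shear=r["cumulative_shear"])
                )
    return pd.DataFrame(rows)


def replace_closure(config: PipelineConfig, fraction: float) -> PipelineConfig:
    cfg = PipelineConfig(**{**config.__dict__})
    cfg.calvarium = replace(config.calvarium, metopic_closure_fraction=fraction)
    return cfg


def closure_trend_diagnostics(sweep: pd.DataFrame) -> dict:
    """Metopic trend slope + max relative change of the other sutures."""
    out = {}
    for case in sweep["case"].unique():
        sub = sweep[sweep["case"] == case]
        met = sub[sub["suture"] == "metopic"].sort_values("fraction")
        mags = np.abs(met["cross_axial"].to_numpy())
        monotone = bool(np.all(np.diff(mags) < 0)) if len(mags) > 1 else False
        slope = float(np.polyfit(met["fraction"], mags, 1)[0]) if len(mags) > 1 else np.nan
        metopic_change = float(np.ptp(met["cross_axial"].to_numpy()))
        others = sub[sub["suture"] != "metopic"]
        changes = {
            sut: float(np.ptp(grp.sort_values("fraction")["cross_axial"].to_numpy()))
            for sut, grp in others.groupby("suture")
        }
        out[case] = {
            "metopic_monotone_decreasing": monotone,
            "metopic_slope_microstrain_per_fraction": slope,
            "metopic_total_change": metopic_change,
            # other sutures should change little compared with the metopic trend
            "max_other_suture_change_vs_metopic": float(
                max(changes.values()) / max(metopic_change, 1e-9)
            ),
            "other_suture_changes": changes,
        }
    return out


def muscle_decomposition(config: PipelineConfig) -> dict:
    """The four single-action sub-cases (temporalis, masseter, medial
    pterygoid — bilateral at working EMG under chewing constraints — and
    palatal pressure alone under suckling constraints), each summarized in
    the per-suture table layout plus a tension/compression sign schematic."""
    mesh = build_calvarium(config.calvarium)
    attachments = default_attachments(mesh)
    solver = fem.CachedSolver(mesh, config.materials)
    sub_cases = ("single:temporalis", "single:masseter", "single:medial_pterygoid",
                 "palatal_pressure_only")
    tables, signs = {}, {}
    for name in sub_cases:
        res = _solve_named_case(mesh, attachments, config, solver, name)
        tables[name] = res.suture_table
        signs[name] = {
            r["suture"]: classify_sign(r["cross_axial"])
            for _, r in res.suture_table.iterrows()
        }
    return {"tables": tables, "sign_schematic": signs, "mesh": mesh}


def classify_sign(value_microstrain: float, floor: float = 1.0) -> str:
    """Tension/compression flag; magnitudes under the 1-microstrain floor
    are left unclassified (the schematic's materiality convention)."""
    if abs(value_microstrain) < floor:
        return "unclassified"
    return "tension" if value_microstrain > 0 else "compression"


def superposition_check(config: PipelineConfig) -> dict:
    """Chewing field vs the sum of its per-muscle-group decomposition under
    identical (chewing) constraints; relative L2 difference should vanish
    by linearity."""
    mesh = build_calvarium(config.calvarium)
    attachments = default_attachments(mesh)
    solver = fem.CachedSolver(mesh, config.materials)

    chew = loads.build_load_case("chewing_R_working", config, mesh, attachments)
    forces_full, dirichlet = loads.realize_loads(chew, mesh)
    dir_resolved = [(mesh.node_sets[s], axes) for s, axes in dirichlet]
    U_full, _ = solver.solve(forces_full, dir_resolved)

    U_sum = np.zeros_like(U_full)
    for group, members in loads.MUSCLE_GROUPS.items():
        sub_forces = np.zeros((mesh.n_nodes, 3))
        for spec in chew.muscle_forces:
            if spec.muscle in members and spec.magnitude > 0:
                sub_forces += fem.point_loads_on_patch(mesh, spec.origin_facets, spec.force)
        U_sub, _ = solver.solve(sub_forces, dir_resolved)
        U_sum += U_sub
    num = np.linalg.norm(U_sum - U_full)
    den = np.linalg.norm(U_full)
    strain_full = fem.recover_strain(mesh, U_full)
    strain_sum = fem.recover_strain(mesh, U_sum)
    sdiff = np.linalg.norm(strain_sum.node_strain - strain_full.node_strain) / np.linalg.norm(
        strain_full.node_strain
    )
    return {"displacement_rel_error": num / den, "strain_rel_error": sdiff}


def sensitivity_material(config: PipelineConfig, E_list=(418.0, 1300.0, 6000.0)) -> dict:
    """Vault-bone Young's modulus sweep; reports Spearman rank correlation of
    the maximum-principal-strain fields across E values and mean ratios."""
    from scipy.stats import spearmanr

    fields, means = [], {}
    for E in E_list:
        if E <= 0:
            raise ValueError("Young's modulus values must be positive")
        cfg = PipelineConfig(**{**config.__dict__})
        mats = dict(config.materials)
        nu = mats["bone"].poisson_ratio
        for region in ("bone", "palate_bone", "face_bone"):
            mats[region] = fem.Material(E, nu)
        cfg.materials = mats
        bundle = run_model(cfg, cases=("chewing_R_working",))
        eps1 = bundle.cases["chewing_R_working"].strain.principal[:, 0] * 1e6
        fields.append((E, eps1))
        means[E] = float(np.abs(eps1).mean())
    correlations = {}
    for i, (a, fa) in enumerate(fields):
        for b, fb in fields[i + 1 :]:
            rho = spearmanr(fa, fb).statistic
            correlations[f"{a:g}_vs_{b:g}"] = float(rho)
    return {"mean_abs_eps1": means, "spearman": correlations}


def sensitivity_boundary(config: PipelineConfig) -> dict:
    """Foramen-magnum constraint on/off and bite-point variants."""
    results = {}
    for fm in (False, True):
        cfg = PipelineConfig(**{**config.__dict__})
        cfg.foramen_magnum_constrained = fm
        bundle = run_model(cfg, cases=("chewing_R_working",))
        res = bundle.cases["chewing_R_working"]
        results[f"foramen_magnum_{'on' if fm else 'off'}"] = res
    # field-difference map between the paired runs
    a = results["foramen_magnum_off"]
    b = results["foramen_magnum_on"]
    diff = np.linalg.norm(a.displacement - b.displacement, axis=1)
    mesh = build_calvarium(config.calvarium)
    argmax = int(np.argmax(diff))
    out = {
        "fm_pair": {
            k: v.suture_table.set_index("suture")["cross_axial"].to_dict()
            for k, v in results.items()
        },
        "fm_diff_max_location": mesh.nodes[argmax].tolist(),
        "fm_diff_max": float(diff.max()),
    }
    bites = {}
    for bite in ("molar1", "molar2", "lateral_incisor"):
        cfg = PipelineConfig(**{**config.__dict__})
        cfg.bite_point = bite
        bundle = run_model(cfg, cases=("chewing_R_working",))
        bites[bite] = bundle.cases["chewing_R_working"].suture_table.set_index("suture")[
            "cross_axial"
        ].to_dict()
    out["bite_variants"] = bites
    return out


# ---------------------------------------------------------------------------
# qualitative regression checks
# ---------------------------------------------------------------------------

_EXPECTED_SIGNS = {
    "metopic": "tension",
    "sagittal": "tension",
    "coronal_L": "compression",
    "coronal_R": "compression",
    "lambdoid_L": "compression",
    "lambdoid_R": "compression",
    "squamous_L": "compression",
    "squamous_R": "compression",
}


def check_sign_schematic(bundle: ResultBundle) -> dict:
    """Tension at metopic/sagittal, compression at coronal/lambdoid/squamous,
    in both behaviors."""
    detail, ok = {}, True
    for case_name, res in bundle.cases.items():
        table = res.suture_table.set_index("suture")
        for suture, expected in _EXPECTED_SIGNS.items():
            if suture not in table.index:
                continue
            got = classify_sign(table.loc[suture, "cross_axial"])
            passed = got == expected
            detail[f"{case_name}:{suture}"] = {
                "expected": expected,
                "observed": got,
                "cross_axial": float(table.loc[suture, "cross_axial"]),
                "pass": passed,
            }
            if got != "unclassified" and not passed:
                ok = False
    return {"pass": ok, "detail": detail}


def check_closure_trend(sweep: pd.DataFrame, other_band: float = 0.25) -> dict:
    """Metopic |cross-axial| strictly decreasing over the sweep; every other
    suture's total change stays below ``other_band`` x the metopic change."""
    diag = closure_trend_diagnostics(sweep)
    ok = all(
        d["metopic_monotone_decreasing"]
        and d["max_other_suture_change_vs_metopic"] < other_band
        for d in diag.values()
    )
    return {"pass": ok, "detail": diag}


def check_profile_minima(profile: analytics.MidlineProfile) -> dict:
    """Patent-model midline eps_zz: the bins adjacent to the nasion end and
    the fontanelle end of the metopic suture are local minima relative to
    the metopic interior."""
    lab = profile.label
    met = lab == "metopic"
    if not met.any():
        return {"pass": False, "detail": "no metopic bins in profile"}
    vals = profile.value
    met_idx = np.flatnonzero(met)
    interior = vals[met_idx]
    edge_n = max(1, len(met_idx) // 5)
    nasion_end = interior[:edge_n].min()
    fontanelle_end = interior[-edge_n:].min()
    peak = interior.max()
    ok = bool(nasion_end < peak and fontanelle_end < peak)
    return {
        "pass": ok,
        "detail": {
            "nasion_end_min": float(nasion_end),
            "fontanelle_end_min": float(fontanelle_end),
            "metopic_interior_max": float(peak),
        },
    }


def check_shear_ranking(bundle: ResultBundle) -> dict:
    """Coronal and squamous cumulative shear exceed metopic cumulative shear
    (patent models, both behaviors)."""
    detail, ok = {}, True
    for case_name, res in bundle.cases.items():
        t = res.suture_table.set_index("suture")["cumulative_shear"]
        met = t.get("metopic", np.nan)
        cor = max(t.get("coronal_L", 0.0), t.get("coronal_R", 0.0))
        sq = max(t.get("squamous_L", 0.0), t.get("squamous_R", 0.0))
        passed = bool(cor > met and sq > met)
        detail[case_name] = {"metopic": float(met), "coronal_max": float(cor),
                             "squamous_max": float(sq), "pass": passed}
        ok = ok and passed
    return {"pass": ok, "detail": detail}


def qualitative_checks(config: PipelineConfig, fractions=(0.0, 0.25, 0.5, 0.75)) -> dict:
    """Run the full qualitative regression battery on the default geometry."""
    bundle = run_model(config)
    sweep = closure_sweep(config, fractions)
    checks = {
        "sign_schematic": check_sign_schematic(bundle),
        "closure_trend": check_closure_trend(sweep),
        "profile_minima": check_profile_minima(
            bundle.cases["chewing_R_working"].profiles["zz"]
        ),
        "shear_ranking": check_shear_ranking(bundle),
    }
    checks["all_pass"] = all(c["pass"] for c in checks.values())
    return checks


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def make_report(bundle: ResultBundle, outdir, checks: dict | None = None,
                write_fields: bool = False, make_plots: bool = False):
    """Write suture tables, profiles, regional stats (CSV), optional VTK
    field exports and profile plots, and a machine-readable check JSON."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for case_name, res in bundle.cases.items():
        safe = case_name.replace(":", "_")
        p = outdir / f"suture_table_{safe}.csv"
        res.suture_table.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
        for comp, prof in res.profiles.items():
            q = outdir / f"profile_{comp}_{safe}.csv"
            pd.DataFrame(
                {"theta_deg": prof.theta, "value_microstrain": prof.value,
                 "suture": prof.label, "n_nodes": prof.count}
            ).to_csv(q, index=False, float_format="%.6g")
            written.append(q)
        r = outdir / f"regional_{safe}.csv"
        res.regional.to_csv(r, index=False, float_format="%.6g")
        written.append(r)
        if res.force_table is not None and len(res.force_table):
            ft = outdir / f"forces_{safe}.csv"
            res.force_table.to_csv(ft, index=False, float_format="%.9g")
            written.append(ft)
        if write_fields:
            v = outdir / f"fields_{safe}.vtk"
            write_vtk(
                bundle.mesh, v,
                point_data={
                    "displacement": res.displacement,
                    "eps1_microstrain": res.strain.principal[:, 0] * 1e6,
                    "von_mises": res.stress.von_mises,
                },
            )
            written.append(v)
        if make_plots:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(7, 3.2))
            prof = res.profiles["zz"]
            for sut in analytics.MIDLINE_SUTURES:
                sel = prof.label == sut
                if sel.any():
                    ax.plot(prof.theta[sel], prof.value[sel], "o-", ms=3, label=sut)
            ax.set_xlabel("theta (deg)")
            ax.set_ylabel("eps_zz (microstrain)")
            ax.legend(fontsize=6)
            ax.set_title(f"midline profile, {case_name}")
            fig.tight_layout()
            f = outdir / f"profile_zz_{safe}.png"
            fig.savefig(f, dpi=120)
            plt.close(fig)
            written.append(f)
    meta = {
        "mesh_hash": bundle.mesh_hash,
        "provenance": bundle.provenance,
        "equilibrium": {k: v.equilibrium for k, v in bundle.cases.items()},
    }
    if checks is not None:
        meta["checks"] = checks
    j = outdir / "report.json"
    with open(j, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    written.append(j)
    return written
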