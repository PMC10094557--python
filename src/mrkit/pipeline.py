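"""End-to-end molecular-replacement driver.

Pipeline: Wilson normalization -> active-reflection selection ->
asymmetric-unit composition -> anisotropy correction -> per copy:
rotation search, FFT translation preselection, TFOM ranking, simplex
refinement, R/clash scoring and the copy-acceptance rules -> solution
ranking by minimum R, with the low-identity alaninization/restart
strategy on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import anisotropy as aniso_mod
from .cell import UnitCell
from .composition import CompositionEstimate, estimate_chain_count, estimate_model_copies
from .model import AtomicModel
from .pose import Pose, apply_pose
from .refine import SearchConfig, Solution, accept_copy, alaninize, clash_fraction, simplex_refine
from .reflections import ReflectionSet, normalize
from .rotation import (
    build_molecular_transform, euler_to_matrix, generate_rotation_grid,
    orientation_expected_matrix, search_orientations,
)
from .scoring import r_factor
from .sfcalc import atom_weights, calc_structure_factors, symmetry_coefficients
from .symmetry import SpaceGroup
from .translation import (
    TranslationCandidate, detect_pseudo_translation, pick_translations,
    tfom_corr, tfom_pst, translation_fft,
)

__all__ = ["RunResult", "run_mr", "write_outputs"]


@dataclass
class RunResult:
    success: bool
    reason: str
    solutions: list[Solution]
    best: Solution | None
    placed_model: AtomicModel | None
    composition: CompositionEstimate | None
    aniso_field: object | None
    pst: tuple[bool, np.ndarray] | None
    refl: ReflectionSet | None
    log: list[str]
    restarted: bool = False
    nmod: int = 0


def _select_active(refl: ReflectionSet, cfg: SearchConfig, moltype: str) -> np.ndarray:
    act = np.ones(len(refl), bool)
    consider_si = moltype == "protein"
    if not (consider_si and cfg.si < 0.5):
        act &= refl.d <= cfg.d_max_active
    act &= refl.d >= cfg.d_min_active
    e = np.sqrt(refl.e2)
    act &= (e <= cfg.e_max) & (e >= cfg.e_min)
    return act


def _place_all(model0: AtomicModel, poses: list[Pose], cell: UnitCell) -> list[AtomicModel]:
    return [apply_pose(model0, p, cell) for p in poses]


def _combined_f(models: list[AtomicModel], cell, sg, hkl) -> np.ndarray:
    total = np.zeros(len(hkl), complex)
    for mdl in models:
        total += calc_structure_factors(mdl, cell, sg, hkl)
    return total


def _score_tfom(refl, f_total_active, variant: str) -> float:
    if variant == "pst":
        return tfom_pst_on_active(refl, f_total_active)
    return tfom_corr(refl.fobs[refl.active], f_total_active)


def tfom_pst_on_active(refl: ReflectionSet, f_active: np.ndarray) -> float:
    """Pseudo-translation TFOM evaluated on the active subset."""
    act = refl.active
    weak = np.sqrt(refl.e2[act]) < 0.3
    if weak.sum() < 30:
        return tfom_corr(refl.fobs[act], f_active)
    from .reflections import calc_e2
    ep2 = calc_e2(np.abs(f_active) ** 2, refl.shell[act])
    return float(1.0 - ep2[weak].mean())


def _pose_objective(refl, model0, cell, sg, located_f_active, variant):
    """TFOM of (located copies + one movable copy) as a function of the pose."""
    act = refl.active
    hkl_a = refl.hkl[act]
    x0, weights = atom_weights(model0, cell, hkl_a)

    def objective(pose: Pose) -> float:
        w = pose.matrix()
        xf = (model0.xyz @ w.T) @ cell.frac.T
        coeff, h_rot = symmetry_coefficients(xf, weights, sg, hkl_a)
        f = (coeff * np.exp(2j * np.pi * (h_rot @ pose.tfrac))).sum(axis=0)
        if located_f_active is not None:
            f = f + located_f_active
        return _score_tfom(refl, f, variant)

    return objective


def run_mr(
    refl: ReflectionSet,
    model: AtomicModel,
    sequences=None,
    cfg: SearchConfig | None = None,
    moltype: str | None = None,
    _is_restart: bool = False,
) -> RunResult:
    """Run the full molecular-replacement search.

    ``refl`` carries cell and space group; ``model`` is the search model in
    orthogonal coordinates; ``sequences`` (target chains) drive the
    composition estimate and may be None to skip it.
    """
    cfg = cfg or SearchConfig()
    cell, sg = refl.cell, refl.sg
    moltype = moltype or model.moltype
    log: list[str] = [f"seed={cfg.seed} dtheta={cfg.dtheta} si={cfg.si:.2f}"]

    def fail(reason: str) -> RunResult:
        log.append(f"FAILURE: {reason}")
        return RunResult(False, reason, [], None, None, None, None, None, None, log)

    # --- normalization and working set -----------------------------------
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refl = normalize(refl)
    except ValueError as exc:
        return fail(f"normalization failed: {exc}")
    refl.active = _select_active(refl, cfg, moltype)
    n_active = int(refl.active.sum())
    log.append(f"active reflections: {n_active}/{len(refl)}")
    if n_active < 50:
        return fail(f"only {n_active} active reflections")

    # --- composition ------------------------------------------------------
    comp = None
    nmod = cfg.nmod
    if sequences is not None:
        try:
            comp = estimate_chain_count(cell, sg, sequences, moltype)
            comp = estimate_model_copies(comp, sequences, model, moltype)
        except ValueError as exc:
            return fail(f"composition estimate failed: {exc}")
        log.append(f"NCHT={comp.ncht} NMOD={comp.nmod} VOLAT={comp.volat:.1f}")
        if nmod is None:
            nmod = comp.nmod
    nmod = nmod or 1

    # --- anisotropy -------------------------------------------------------
    field = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = aniso_mod.analyze(refl)
        if field.significant:
            refl = aniso_mod.apply_correction(refl, field)
            log.append(f"anisotropy correction applied (system={field.system})")
    except ValueError as exc:
        log.append(f"anisotropy analysis skipped: {exc}")

    # --- pseudo-translation ----------------------------------------------
    pst_flag, pst_vec = detect_pseudo_translation(refl)
    variant = "pst" if pst_flag else "corr"
    if pst_flag:
        log.append(f"pseudo-translation detected at {np.round(pst_vec, 3)}")

    # --- search model preparation ----------------------------------------
    search_model = model
    if moltype == "protein" and cfg.si < cfg.restart_si and not _is_restart:
        search_model = alaninize(model, cfg.ala_fraction)
        log.append(f"low SI: alaninized {cfg.ala_fraction:.0%} of residues up front")
    nonh = np.array([str(e).strip().upper() != "H" for e in search_model.element])
    model0 = search_model.select(nonh).centered()
    d_min_act = float(refl.d[refl.active].min())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        transform = build_molecular_transform(model0, d_min_act)
    grid = generate_rotation_grid(sg, cfg.dtheta, "bcc", cell)
    log.append(f"rotation grid: {len(grid.points)} points (bcc, {cfg.dtheta} deg)")
    exp_matrix = orientation_expected_matrix(refl, transform, grid, sg)

    act = refl.active
    hkl_a = refl.hkl[act]
    fobs_a = refl.fobs[act]
    x_dummy, weights_a = atom_weights(model0, cell, hkl_a)

    def score_solution(sol: Solution) -> Solution:
        placed = _place_all(model0, sol.poses, cell)
        f_act = _combined_f(placed, cell, sg, hkl_a)
        sol.r = r_factor(fobs_a, np.abs(f_act))
        sol.tfom = _score_tfom(refl, f_act, variant)
        sol.clash = clash_fraction(placed, cell, sg) if placed else 0.0
        return sol

    carried: list[Solution] = [Solution(poses=[])]
    prev_best_tfom = -np.inf
    final: list[Solution] = []

    for copy_i in range(1, nmod + 1):
        candidates: list[tuple[Solution, Pose, float]] = []
        for sol in carried:
            if sol.poses:
                placed = _place_all(model0, sol.poses, cell)
                located_f = _combined_f(placed, cell, sg, refl.hkl)
                located_f_a = located_f[act]
            else:
                located_f = located_f_a = None
            orients = search_orientations(refl, transform, located_f, grid, sg,
                                          n_keep=cfg.n_keep_rot, expected_matrix=exp_matrix)
            for oc in orients:
                w = np.asarray(oc.euler, float)
                xf = (model0.xyz @ euler_to_matrix(w).T) @ cell.frac.T
                coeff, h_rot = symmetry_coefficients(xf, weights_a, sg, hkl_a)
                try:
                    tmap = translation_fft(refl, xf, weights_a, sg, located_f=located_f)
                except ValueError:
                    continue
                for tf in pick_translations(tmap, sg, k=cfg.n_keep_trans, first_copy=not sol.poses):
                    f = (coeff * np.exp(2j * np.pi * (h_rot @ tf))).sum(axis=0)
                    if located_f_a is not None:
                        f = f + located_f_a
                    tf_score = _score_tfom(refl, f, variant)
                    candidates.append((sol, Pose(w.copy(), tf), tf_score))
        if not candidates:
            if copy_i == 1:
                return fail("no translation candidates found")
            break
        candidates.sort(key=lambda c: -c[2])
        refined: list[Solution] = []
        for parent, pose, tf_score in candidates[: cfg.n_refine]:
            if tf_score <= 0 and copy_i == 1 and len(refined) > 0:
                break
            if parent.poses:
                placed = _place_all(model0, parent.poses, cell)
                lfa = _combined_f(placed, cell, sg, hkl_a)
            else:
                lfa = None
            objective = _pose_objective(refl, model0, cell, sg, lfa, variant)
            new_pose, new_score = simplex_refine(pose, objective)
            cand = Solution(poses=[p.copy() for p in parent.poses] + [new_pose])
            cand = score_solution(cand)
            cand.rfom = tf_score
            if copy_i > 1:
                ok, tag = accept_copy(parent.r, cand.r, cand.clash, cfg)
                cand.rule = tag
                log.append(
                    f"copy {copy_i}: R {parent.r:.3f}->{cand.r:.3f} clash {cand.clash:.2f} "
                    f"tfom {cand.tfom:.3f} rule={tag} {'accept' if ok else 'reject'}"
                )
                if not ok:
                    continue
            refined.append(cand)
        if not refined:
            log.append(f"copy {copy_i}: all candidates rejected; stopping")
            break
        best_tfom = max(s.tfom for s in refined)
        if copy_i > 1 and best_tfom < prev_best_tfom:
            log.append(
                f"copy {copy_i}: best TFOM {best_tfom:.3f} < previous {prev_best_tfom:.3f}; stopping"
            )
            break
        prev_best_tfom = best_tfom
        refined.sort(key=lambda s: s.r)
        carried = refined[: cfg.n_carry]
        final = carried
        log.append(f"copy {copy_i}: carried {len(carried)} solutions, best R={carried[0].r:.3f}")
        if copy_i < nmod:
            # located copies lose rigidity downstream; approximate by
            # re-refining each placed pose before the next search
            for sol in carried:
                for pi in range(len(sol.poses)):
                    others = [p for j, p in enumerate(sol.poses) if j != pi]
                    placed = _place_all(model0, others, cell)
                    lfa = _combined_f(placed, cell, sg, hkl_a) if others else None
                    objective = _pose_objective(refl, model0, cell, sg, lfa, variant)
                    sol.poses[pi], _ = simplex_refine(sol.poses[pi], objective, rot_step=1.0,
                                                      trans_step=0.01, maxiter=150)
                score_solution(sol)

    if not final:
        return fail("no acceptable solutions")

    final.sort(key=lambda s: s.r)
    # joint polish of the leading multi-copy solution: each pose re-refined
    # against the others before the final ranking
    if len(final[0].poses) > 1:
        top = final[0]
        for pi in range(len(top.poses)):
            others = [p for j, p in enumerate(top.poses) if j != pi]
            lfa = _combined_f(_place_all(model0, others, cell), cell, sg, hkl_a)
            objective = _pose_objective(refl, model0, cell, sg, lfa, variant)
            top.poses[pi], _ = simplex_refine(top.poses[pi], objective,
                                              rot_step=1.0, trans_step=0.01, maxiter=200)
        score_solution(top)
        final.sort(key=lambda s: s.r)
    for rank, sol in enumerate(final, start=1):
        sol.rank = rank
    best = final[0]

    restarted = False
    if (not _is_restart and moltype == "protein"
            and best.r > cfg.restart_r and cfg.si < cfg.restart_si):
        log.append(f"best R {best.r:.3f} > {cfg.restart_r} at low SI: restarting fully alaninized")
        retry = run_mr(refl, alaninize(model, 1.0), sequences, cfg, moltype, _is_restart=True)
        if retry.success and retry.best is not None and retry.best.r < best.r:
            retry.restarted = True
            retry.log = log + retry.log
            return retry
        restarted = True

    placed = _place_all(model0, best.poses, cell)
    combined = _combine_model(placed)
    log.append(f"done: {len(best.poses)} copies, best R={best.r:.3f} tfom={best.tfom:.3f}")
    return RunResult(True, "ok", final, best, combined, comp, field,
                     (pst_flag, pst_vec), refl, log, restarted, nmod)


def _combine_model(placed: list[AtomicModel]) -> AtomicModel:
    """Concatenate placed copies with re-lettered chains."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    parts = []
    for i, mdl in enumerate(placed):
        part = mdl.copy()
        part.chain = np.array([letters[i % 26]] * part.n_atoms, object)
        parts.append(part)
    first = parts[0]
    return AtomicModel(
        np.concatenate([p.element for p in parts]),
        np.concatenate([p.xyz for p in parts]),
        np.concatenate([p.b_iso for p in parts]),
        np.concatenate([p.occ for p in parts]),
        np.concatenate([p.chain for p in parts]),
        np.concatenate([p.resseq for p in parts]),
        np.concatenate([p.resname for p in parts]),
        np.concatenate([p.name for p in parts]),
        first.moltype,
    )


def write_outputs(result: RunResult, out_dir: str, cell: UnitCell, sg: SpaceGroup) -> None:
    """Emit positioned model (PDB), solution table (TSV) and run log."""
    import os

    from .model import write_pdb

    os.makedirs(out_dir, exist_ok=True)
    if result.placed_model is not None:
        write_pdb(result.placed_model, os.path.join(out_dir, "positioned.pdb"), cell, sg.symbol)
    with open(os.path.join(out_dir, "solutions.tsv"), "w") as fh:
        fh.write("rank\tcopy\talpha\tbeta\tgamma\ttx\tty\ttz\trfom\ttfom\tclash\tR\trule\n")
        for sol in result.solutions:
            for ci, pose in enumerate(sol.poses, start=1):
                fh.write(
                    f"{sol.rank}\t{ci}\t"
                    + "\t".join(f"{v:.3f}" for v in pose.euler)
                    + "\t" + "\t".join(f"{v:.4f}" for v in pose.tfrac)
                    + f"\t{sol.rfom:.4f}\t{sol.tfom:.4f}\t{sol.clash:.3f}\t{sol.r:.4f}\t{sol.rule}\n"
                )
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(result.log) + "\n")
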