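"""Project prediction accuracy and coverage onto a spherical grid.

Gaussian-process smoothing of per-electrode values (per subject, then
combined) onto an order-4 icosphere; writes x/y/z/value TSVs under
results/surface/.
"""
from pathlib import Path

import numpy as np

from semenc import encoding, pipeline, surface
from semenc.datatypes import GpConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "surface"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = pipeline.simulate_experiment(seed=SEED)
    fit = encoding.fit_ridge_cv(
        study.features, study.residual_recording.hfb, study.plan, time_shift=0.32
    )
    grid = surface.icosphere_grid(order=4, radius=100.0)
    cfg = GpConfig(sigma=8.0, eta=1e-3)

    acc_maps, cov_maps = [], []
    for s in np.unique(study.geometry.subject_of):
        idx = np.flatnonzero(study.geometry.subject_of == s)
        xyz = study.geometry.sphere_xyz[idx]
        acc = surface.gp_project(fit.r_cv[idx], xyz, grid, cfg)
        # a subject only informs grid points near their own electrodes
        dist = surface.distance_matrix(xyz, grid.points, grid.radius)
        acc[dist.min(axis=0) > 3 * cfg.sigma] = np.nan
        acc_maps.append(acc)
        cov_maps.append(surface.gp_project(np.ones(idx.size), xyz, grid, cfg))
    accuracy = surface.combine_subjects(acc_maps, mode="mean")
    density = surface.combine_subjects(cov_maps, mode="density")
    for name, vals in (("accuracy", accuracy), ("coverage_density", density)):
        np.savetxt(OUT / f"{name}.tsv",
                   np.column_stack([grid.points, vals]), delimiter="\t",
                   header="x\ty\tz\tvalue", comments="")
    print(f"projected {study.geometry.n_electrodes} electrodes from "
          f"{study.geometry.n_subjects} subjects onto {grid.points.shape[0]} "
          f"grid points; peak smoothed accuracy {np.nanmax(accuracy):.3f}")


if __name__ == "__main__":
    main()
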