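#!/usr/bin/env python
"""Juvenile-versus-adult comparative analyses on the synthetic study.

For each clade with at least three species whose HOST rejects slope
homogeneity: the ontogenetic convergence/divergence D test. Then
multivariate phylogenetic signal (K) per stage with the dK contrast, the
simulation-based phylogenetic MANOVA per stage, and phylomorphospace
coordinates of the adult shapes.

Writes: d_test.tsv, signal.tsv, manova.tsv, phylomorphospace_nodes.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ontotraj.allometry import fit_unique_allometries, host_test
from ontotraj.config import RunConfig
from ontotraj.morphometry import ShapeData
from ontotraj.stages import (
    d_test,
    delta_k_test,
    k_mult,
    pca_scores,
    phylo_manova,
    phylomorphospace,
    stage_means,
)
from ontotraj.trees import read_newick


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--permutations", type=int, default=999)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed, n_permutations=args.permutations)

    df = pd.read_csv(args.out / "shapes.csv")
    shape = ShapeData(
        Y=df.drop(columns=["size", "species"]).to_numpy(),
        size=df["size"].to_numpy(),
        species=df["species"].to_numpy(),
        sex=np.array(["M"] * len(df)),
    )
    tree = read_newick((args.data / "tree.nwk").read_text())
    habitat = pd.read_csv(args.data / "habitat.csv").set_index("species")
    fit, traj = fit_unique_allometries(shape)
    sm = stage_means(traj, fit)

    # D test per clade that rejects slope homogeneity
    rows = []
    clades = {"all": tree.tip_labels}
    clades.update({
        f"clade_{i}": tips
        for i, (nd, tips) in enumerate(tree.clades(3).items())
        if len(tips) >= 3
    })
    for name, tips in clades.items():
        host = host_test(shape, species=tips, config=cfg)
        if host.p >= cfg.alpha:
            rows.append({"clade": name, "n_species": len(tips),
                         "host_p": host.p, "D": np.nan, "p": np.nan})
            continue
        res = d_test(shape, fit, traj, clade_species=tips, config=cfg,
                     host_p=host.p)
        rows.append({"clade": name, "n_species": len(tips), "host_p": host.p,
                     "D": res.D, "p": res.p})
    dtab = pd.DataFrame(rows)
    dtab.to_csv(args.out / "d_test.tsv", sep="\t", index=False)

    # phylogenetic signal per stage and per trajectory attribute
    order = tree.tip_labels
    idx = [sm.species.index(s) for s in order]
    sig_rows = []
    for name, mat in (
        ("juvenile_shape", sm.juvenile[idx]),
        ("adult_shape", sm.adult[idx]),
        ("trajectory_length", traj.lengths[idx][:, None]),
        ("slopes", fit.slopes[idx]),
    ):
        K, p = k_mult(tree, mat, n_permutations=cfg.n_permutations,
                      rng=cfg.rng(f"kmult:{name}"))
        sig_rows.append({"matrix": name, "K": K, "p": p})
    dK, Ka, Kj, pk = delta_k_test(tree, shape, traj, cfg)
    sig_rows.append({"matrix": "delta_K (adult - juvenile)", "K": dK, "p": pk})
    sig = pd.DataFrame(sig_rows)
    sig.to_csv(args.out / "signal.tsv", sep="\t", index=False)

    # phylogenetic MANOVA per stage
    man_rows = []
    for stage, mat, size_col, hab_col in (
        ("juvenile", sm.juvenile, sm.juvenile_size, "juvenile_habitat"),
        ("adult", sm.adult, sm.adult_size, "adult_habitat"),
    ):
        hab = habitat.loc[sm.species, hab_col].to_numpy()
        res = phylo_manova(tree, mat, size_col, hab, species=sm.species,
                           config=cfg)
        res.insert(0, "stage", stage)
        man_rows.append(res)
    man = pd.concat(man_rows, ignore_index=True)
    man.to_csv(args.out / "manova.tsv", sep="\t", index=False)

    # phylomorphospace of adult shape (first two PCs)
    Xc = sm.adult - sm.adult.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = Xc @ Vt[:2].T
    nodes, edges = phylomorphospace(tree, pcs, tip_labels=sm.species)
    nodes.to_csv(args.out / "phylomorphospace_nodes.tsv", sep="\t")
    edges.to_csv(args.out / "phylomorphospace_edges.tsv", sep="\t", index=False)

    div = dtab[(dtab["D"] < 0) & (dtab["p"] < cfg.alpha)]
    conv = dtab[(dtab["D"] > 0) & (dtab["p"] < cfg.alpha)]
    print(f"D test on {len(dtab)} clades: {len(div)} diverge, {len(conv)} converge")
    print(sig.to_string(index=False))
    print(f"MANOVA significant terms: "
          f"{man[man['p'] < cfg.alpha][['stage', 'term', 'p']].to_dict('records')}")


if __name__ == "__main__":
    main()
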