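#!/usr/bin/env python
"""Test fitted regulatory parameters for phylogenetic signal.

For each (log-scaled) parameter, estimates Pagel's lambda on the strain
tree with a simulated-null likelihood-ratio test; also Mantel-tests the
association between patristic distance and landscape-shape distance, and
runs the PD bootstrap to check whether a strain subset is representative
of the collection.  Parameters sampled independently of the tree should
show no signal; this stage is the negative control of the synthetic study.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lacreg import io as lio
from lacreg.model import landscape_distance
from lacreg.phylo import (TraitVector, mantel_test, pagel_lambda_test,
                          pagel_null_reference, patristic_matrix,
                          pd_representativeness, tree_from_newick)
from lacreg.simulate import transform_params_table

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bundle", type=Path, default=Path("results/bundle"))
    ap.add_argument("--fits", type=Path, default=Path("results/fits.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    tree = tree_from_newick((args.bundle / "tree_core.nwk").read_text())
    params = transform_params_table(
        pd.read_csv(args.fits, index_col=0).drop(columns=["rmse"]))
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = pagel_null_reference(tree, labels, n_sim=499, seed=args.seed)
    rows = []
    for pname in params.columns:
        tv = TraitVector(labels, params.loc[labels, pname].to_numpy())
        res = pagel_lambda_test(tree, tv, null_ref=ref)
        rows.append({"parameter": pname, **res.to_dict()})
        print(f"{pname:8s} lambda={res.lambda_pagel:.2f} p={res.p_value:.3f}")
    pd.DataFrame(rows).to_csv(args.out_dir / "phylo_signal.csv", index=False)

    landscapes = {ls.strain_id: ls for ls in
                  lio.read_expression_csv(args.bundle / "expression.csv")}
    tips, D = patristic_matrix(tree, labels)
    k = len(tips)
    ld = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ld[i, j] = ld[j, i] = landscape_distance(landscapes[tips[i]],
                                                     landscapes[tips[j]])
    r, p = mantel_test(D, ld, n_perm=999, seed=args.seed)
    print(f"phylogeny vs landscape shape: Mantel r={r:.2f}, p={p:.3f}")

    subset = labels[: max(4, len(labels) // 3)]
    pd_val, pd_p = pd_representativeness(tree, subset, n_draws=1000,
                                         seed=args.seed)
    print(f"PD of {len(subset)}-strain subset: {pd_val:.3f} "
          f"(bootstrap p={pd_p:.3f})")
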