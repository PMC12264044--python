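"""Proteomics stage: differential sets, secretome, pathways, interactome.

Simulates the three-cell-type abundance matrix (CTM myofibroblasts, STC
stromal cells, LSK progenitors; 6 biological × 3 technical each) with
planted CTM-enriched secreted ligands, then runs the full downstream
chain: technical-replicate collapse → lowest-value imputation → pairwise
differential abundance (FC > 2, BH p < 0.05) → Venn counts → secretome →
pathway classification → ligand-receptor interaction scores.  Writes
tables under results/proteomics/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from spleenniche import proteo as pr
from spleenniche import synthgeom as sg

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/proteomics")
OUT.mkdir(parents=True, exist_ok=True)

# planted truth: 120 CTM-enriched (40 secreted), 60 STC-enriched (20 secreted)
ctm_up = [f"P{i:05d}" for i in range(120)]
stc_up = [f"P{i:05d}" for i in range(120, 180)]
eff = pd.concat([
    pd.DataFrame({"CTM": [2.0] * 120}, index=ctm_up),
    pd.DataFrame({"STC": [2.0] * 60}, index=stc_up),
]).fillna(0.0)
matrix = sg.simulate_abundance(2431, {"CTM": 6, "STC": 6, "LSK": 6},
                               effects=eff, missing_rate=0.05,
                               seed=SEED, n_tech=3)

imputed = pr.impute_lowest(pr.collapse_technical(matrix))
de = {}
for a, b in (("CTM", "STC"), ("LSK", "STC"), ("LSK", "CTM")):
    de[f"{a}_vs_{b}"] = pr.differential_abundance(imputed, a, b)
    de[f"{a}_vs_{b}"].to_csv(OUT / f"de_{a}_vs_{b}.csv")
    n = int(de[f"{a}_vs_{b}"]["enriched"].sum())
    print(f"{a} vs {b}: {n} differentially abundant proteins")

venn = pr.pairwise_sets(de)
(OUT / "venn.json").write_text(json.dumps(venn["counts"], indent=2,
                                          sort_keys=True))
print("venn counts:", venn["counts"])

# annotation: secreted flags on a subset of planted + background proteins
rng = np.random.default_rng(SEED + 1)
secretory = {p: True for p in ctm_up[:40] + stc_up[:20]}
secretory.update({f"P{i:05d}": True for i in rng.integers(200, 2431, 100)})
receptors = [f"P{i:05d}" for i in range(1000, 1080)]
pathway_rows = [dict(protein=p, pathway_id=f"pw{k:03d}")
                for k, p in enumerate(receptors)]
for k, lig in enumerate(ctm_up[:40] + stc_up[:20]):
    pathway_rows.append(dict(protein=lig, pathway_id=f"pw{k % 80:03d}"))
ann = pr.AnnotationBundle(secretory=secretory,
                          pathways=pd.DataFrame(pathway_rows),
                          lr_pairs=pd.DataFrame(
                              {"ligand": ctm_up[:10] + stc_up[:5],
                               "receptor_monomers": receptors[:15]}))

ctm_sec = pr.secretome_subset(
    set(de["CTM_vs_STC"].index[de["CTM_vs_STC"]["enriched_up"]]), ann)
stc_sec = pr.secretome_subset(
    set(de["CTM_vs_STC"].index[de["CTM_vs_STC"]["enriched_down"]]), ann)
print(f"secretome: {len(ctm_sec)} CTM-enriched, {len(stc_sec)} STC-enriched "
      "secreted proteins")

lsk_detected = set(matrix.values.index[
    matrix.values[matrix.columns_for("LSK")].notna().any(axis=1)])
classes = pr.pathway_classes(ctm_sec, stc_sec, lsk_detected, ann)
classes.to_csv(OUT / "pathway_classes.csv", index=False)
print("LSK pathway classes:", classes["class"].value_counts().to_dict())

scores = pd.concat([pr.interaction_scores(imputed, ann.lr_pairs, sender,
                                          n_perm=1000, seed=SEED + 2)
                    for sender in ("CTM", "STC")], ignore_index=True)
scores.to_csv(OUT / "interactions.csv", index=False)
sig = scores[scores["p"] < 0.05]
print(f"interactome: {len(sig)}/{len(scores)} pairs significant at p<0.05; "
      f"CTM mean score {scores.loc[scores['sender'] == 'CTM', 'score'].mean():.2f} "
      f"vs STC {scores.loc[scores['sender'] == 'STC', 'score'].mean():.2f}")
print(f"wrote {OUT}")
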