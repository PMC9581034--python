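# dgann

Quality assessment of protein–protein docking decoys with a graph-attention
ensemble.

A docking decoy is converted into a residue-level contact graph over the
whole model (an edge wherever any two inter-residue atoms sit closer than
5 Å), each residue encoded as a 26-D vector (5 physico-chemical factor
scores + 20 sequence-profile scores + information content). A small network
of stacked graph-attention layers scores every residue, pools the top-k
interface residues into a fixed-size representation, and emits the decoy's
probability of being near-native. To cope with the extreme class imbalance
of docking decoy sets, many classifiers are trained on balanced bootstrap
subsets (all positives + an equal per-target draw of negatives) and their
scores combined by mean or max. Ranking quality is measured with
enrichment factors (EF at percentage checkpoints, bounded by
EF_max = decoys/positives) and success rates at top-N.

Decoys are labeled against the native complex with the binary rule:
*incorrect* iff `fnat < 0.1` or (`lRMSD > 10` and `iRMSD > 4`); everything
else is near-native (positive).

The network is implemented directly in NumPy with hand-derived gradients
(validated against finite differences in the test suite); there is no deep
learning framework dependency.

## Layout

| module | contents |
|---|---|
| `dgann.structure` | PDB I/O, receptor/ligand chain partitioning |
| `dgann.quality` | fnat, iRMSD, lRMSD (Kabsch superposition), binary label |
| `dgann.graphs` | residue contact graph + interface mask, JSON container |
| `dgann.features` | five-factor table, PSSM reader, IC, fallback profiles |
| `dgann.model` | GAT layers, top-k sort pooling, scoring head, backprop |
| `dgann.training` | identity clustering, CV splits, bootstrap subsets, Adam, ensembling |
| `dgann.evaluation` | EF / EF_max / success rate / fold aggregation |
| `dgann.simulate` | synthetic natives + rigid-body decoys with known ground truth |

## CLI

```sh
dgann simulate --out scratch/sim --seed 1            # synthetic decoy sets
dgann label    --native T000/native.pdb --decoys T000/ --out labels.tsv
dgann graphify --native T000/native.pdb --decoys T000/ \
               --labels labels.tsv --out graphs/T000
dgann train    --config train.yaml --out ckpts/     # bootstrap ensemble
dgann score    --checkpoints ckpts/ --graphs graphs/T000 --out scores.tsv
dgann evaluate --scores scores.tsv --labels labels.tsv --out report.json
```

`train.yaml` names `graphs_dir`, `train_targets`, `val_targets`,
`n_subsets`, and optional `hyper:`/`training:` blocks (layer count, k,
attention mode `dot`/`gat_v1`, readout `topk`/`mean`/`max`, learning rate,
patience, …).

Per-chain PSI-BLAST ASCII PSSMs (`-out_ascii_pssm`) may be supplied to
`graphify`; without them a deterministic BLOSUM62-based fallback profile is
used so the pipeline runs fully offline.

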