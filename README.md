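# fragsite

Template-based prediction of NAD-/FAD-binding residues in protein
structures. Binding sites of known cofactor-bound structures are turned into
moiety-typed residue templates (nicotinamide or flavin / adenosine /
phosphate); query structures are searched for local matches by rigidly
superposing every backbone N–Cα–C triplet onto every template triplet and
single-linkage clustering the mutually consistent transforms. Each cluster
is scored by a composite of aligned-residue count, Cα RMSD, BLOSUM62
sequence similarity and secondary-structure similarity; predicted ligand
moiety centers are back-projected into query coordinates and nearby
cross-moiety predictions reinforce each other. Per-protein z-normalized
scores are thresholded either at a pooled 5% false-positive rate or at the
maximum-MCC operating point.

## Layout

| module | role |
| --- | --- |
| `fragsite.structure_io` | PDB / DSSP reading, backbone triplets, fallback secondary-structure assignment |
| `fragsite.template_db` | moiety decomposition, binding-residue templates, JSON-lines database, composition statistics |
| `fragsite.fragment_align` | triplet superposition (Kabsch), transform-grid single-linkage clustering |
| `fragsite.scoring` | composite per-residue binding scores, cross-moiety boost, z-normalization |
| `fragsite.evaluation` | confusion metrics, operating points, leave-one-out driver, balanced subsampling, adjacency relabeling |
| `fragsite.synthetic_fixtures` | ideal backbones, planted binding sites, toy benchmark datasets |
| `fragsite.cli` | `fragsite` command-line interface |

## CLI

```sh
# write a synthetic toy dataset (PDB files + annotations + manifest)
fragsite simulate --n-proteins 10 --seed 42 --outdir toy/

# build a template database from ligand-bound structures
fragsite build-db toy/*.pdb --out toy/db.jsonl

# score a query structure
fragsite predict toy/syn000.pdb --db toy/db.jsonl --out pred.tsv

# leave-one-out evaluation over a dataset manifest
fragsite evaluate --manifest toy/manifest.tsv --outdir eval/
```

All tunables (contact cutoff 3.5 Å, cluster threshold D₀ = 2.0 Å, RMSD
bound 3.0 Å, boost window [3, 9] Å, 5% FPR cap, …) can be set in a YAML
config passed via `--config`; command-line flags override file values.

Real datasets require externally prepared inputs: PDB structures of
cofactor-bound chains (redundancy-filtered, e.g. with CD-HIT at 40%
identity), optional DSSP output files, and a whitespace-delimited
binding-annotation table (`pdb chain ligand G12 R15 …`, BioLiP-style).
Without an annotation table, binding residues are identified geometrically
(any atom within the contact cutoff of a moiety atom).

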