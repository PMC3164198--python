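# idomain

Trajectory analysis of **integrin α-subunit I-domain conformational
stability** and of forced receptor–ligand unbinding.

The α I domain (~180–190 residues, Rossmann fold) sits atop the α subunit
of β₂ integrins such as LFA-1 (α_Lβ₂) and Mac-1 (α_Mβ₂) and binds ICAM-1
through a metal-ion-dependent adhesion site (MIDAS). Its affinity state —
low (LA), intermediate (IA) or high (HA) — is signalled by an axial,
downward displacement of the C-terminal α7 helix of roughly 8–11 Å per
residue, accompanied by MIDAS re-orientation and by re-zippering of a
hydrophobic junction between the α1 and α7 helices. This package provides
the quantitative observables needed to read those signatures off
molecular-dynamics output, and a classifier that turns repeated
equilibration runs into a census over four conformational categories.

## What it computes

For a trajectory `X(t)` with topology in author (PDB) numbering:

* **Global RMSD** — per frame, least-squares (Kabsch) superposition of a
  backbone selection (N, CA, C, O) onto a crystal reference and the RMSD
  of that same selection: whole-domain stability.
* **Per-residue RMSD** — one global backbone fit per frame, then each
  residue's backbone RMSD in that common frame, averaged over time:
  locates the unstable residues.
* **Segment RMSD vs. multiple references** — fit a configured *stable
  core* onto each reference (LA/IA/HA crystal structure), measure the α7
  segment (E293–K305 for LFA-1) **without refit**. A run that transitions
  LA → HA shows a descending series against the HA reference and an
  ascending one against LA.
* **MIDAS coordination spheres** — a candidate residue is *primary* if
  min over its side-chain oxygens of the distance to the metal ion is
  ≤ 3.5 Å, *secondary* otherwise.
* **Zipper-junction distances** — Cβ–Cβ distances of the α1/α7 residue
  pairs (F153–F292, L161–F299 in LFA-1) that quantify junction closure.
* **Swing-out angle** — angle between the helix vector (Cα K305 → Cα
  E293) of the frame and of the reference, after core superposition.
* **Complex lifetime** — from a constant-force separation trace
  `d(t)` (MIDAS ion to ligand carboxylate oxygen, min over OD1/OD2 or
  OE1/OE2), the first time `d ≥ 10 Å` holds for a dwell of consecutive
  frames; censored if never. Repeats are summarised as mean ± sample SD
  with an explicit censored count.
* **Four-category state classification** of repeated runs from the
  dual-reference α7 RMSD series plus the swing angle: (1) stay-LA,
  (2) swing-in/slight-downward convergence, (3) large downward
  transition, (4) swing-out.

A synthetic-data module generates geometric scaffold templates,
category-labelled trajectories and unbinding traces with known ground
truth, so the whole pipeline is testable without MD output.

## Worked example

```python
import idomain as idm
from idomain.synthetic import TemplateSpec, make_template, make_equilibration, \
    core_spec, alpha7_spec

la = make_template(TemplateSpec(state="LA"))
ha = make_template(TemplateSpec(state="HA"))

# a run undergoing the spontaneous LA -> HA transition, 0.5 A noise
run, truth = make_equilibration(category=3, noise_sigma=0.5, seed=11)

series = idm.segment_rmsd_vs_references(
    run, {"LA": la, "HA": ha}, core_spec(), alpha7_spec())
swing = idm.swing_angle(run, (305, 293), la, core_spec())
call = idm.classify_run(series[0], series[1], swing)
print(call.category, call.label)
print({k: round(v, 2) for k, v in call.evidence.items()})
```

prints

```
3 large-downward-transition
{'tail_la_A': 9.04, 'tail_ha_A': 0.87, 'tail_sd_la_A': 0.07,
 'tail_sd_ha_A': 0.05, 'head_ha_A': 6.33, 'tail_swing_deg': 2.99,
 'gap_A': 8.17, 'ha_drop_A': 5.46}
```

i.e. the run ends ~9 Å from the LA placement and ~0.9 Å from the HA one
(0.87 Å is the noise floor of σ = 0.5 Å isotropic coordinate noise), the
HA-reference series dropped by 5.5 Å from head to tail, and the helix did
not swing out (3° tail angle) — the category-3 signature.

The same analyses run from the shell on PDB/DCD files via the CLI:

```sh
idomain synth template --state LA -o la.pdb
idomain synth equilibration --category 3 --runs 2 -o runs/
idomain stability --config stability.yaml     # RMSD/junction/swing CSVs + census
idomain lifetimes --config lifetimes.yaml     # per-trace lifetimes + summaries
idomain defaults                              # print tunable parameters
```

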