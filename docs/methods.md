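# Methods

## Superposition and RMSD conventions

All fits are unweighted least-squares rigid superpositions (Kabsch;
solved via scipy's `Rotation.align_vectors`, proper rotation enforced, so
a reflection is never returned). RMSD is plain coordinate RMSD over the
selected heavy atoms; no mass weighting (backbone atoms have near-equal
masses and the references carry no hydrogens). The reported RMSD is
recomputed from the transformed coordinates rather than taken from the
solver's residual, which loses precision to cancellation near zero.

The backbone atom set is {N, CA, C, O} — *all* backbone heavy atoms, not
Cα only; the carbonyl oxygen is included deliberately. Atom
correspondence between a trajectory topology and a reference is by
`(chain, author residue number, atom name)`; unmatched atoms are dropped
pairwise with a warning, and losing more than 10% of a selection is an
error because the observable would no longer measure what the selection
names.

Three observables share the fit primitive:

* **global RMSD**: fit = measure = the backbone selection;
* **per-residue RMSD**: one global backbone fit per frame, per-residue
  backbone RMSD measured in that common frame, time-averaged — the
  common frame is what makes residues comparable;
* **segment RMSD vs. references**: fit on the configured *stable core*,
  measure the α7 segment with **no refit**. The segment's displacement
  relative to the core is the affinity-state signal; refitting the
  segment would erase it. Global RMSD is implemented as the fit=measure
  special case of this routine, so the two agree bit-for-bit whenever
  segment = core.

The stable core is a configured residue-range selection (defaults:
residues 170–200 and 250–280 of the synthetic scaffold, i.e. a central
block away from the MIDAS loops and the α7 helix). No iterative
least-mobile-subset refinement is attempted; crystallographic cores for
real systems should be supplied in the config.

## MIDAS coordination spheres

A candidate residue is **primary** when the minimum over its side-chain
oxygens (OG, OG1, OD1, OD2, OE1, OE2, OH; backbone O excluded) of the
distance to the metal ion is ≤ 3.5 Å, **secondary** otherwise. Choices
made where the convention was open:

* the boundary is *inclusive* (≤), avoiding knife-edge label flips at
  exactly 3.5 Å;
* multi-oxygen residues (Asp/Glu) use the *minimum* over their oxygens —
  the natural contact criterion;
* Thr coordinates through OG1 only; water-mediated coordination is out
  of scope (candidate lists name protein residues only);
* a candidate without any side-chain oxygen (e.g. Ala) is a hard error
  naming the residue, because silently skipping it would bias the
  partition.

The label is a step function of the minimum distance with its single
breakpoint at the cutoff, so raising the cutoff can only promote
residues to primary — a property the tests assert.

## Swing-out angle

The helix vector runs from Cα of the C-terminal helix residue to Cα of
the N-terminal one (K305 → E293 in LFA-1 numbering). The frame is first
superposed on the reference via the stable core; the angle between the
rotated frame vector and the reference vector is reported in degrees
(0–180). Measuring after core superposition is a convention of this
package — it makes the angle invariant under global rigid motion and
reads the swing relative to the domain body rather than the lab frame.

## Forced-unbinding lifetime

The rupture criterion "ion separated from the ligand carboxylate oxygen
by about 10 Å" is hardened into: lifetime = time (from trace start, i.e.
force application) of the first frame that begins ≥ `dwell` consecutive
frames with separation ≥ `threshold`. Defaults: threshold 10.0 Å, dwell
10 frames. The dwell suppresses single-frame excursions (transient
rebinding) and makes the statistic deterministic; both parameters are
exposed. The distance is the plain Euclidean atom-centre distance, min
over the two carboxylate oxygens (OD1/OD2 or OE1/OE2), with no ionic
radius correction.

Censoring is explicit: a trace that never satisfies the rule yields a
censored result, summaries report the censored count, and a group that
is entirely censored has no mean rather than a fabricated one. Repeat
summaries use the sample SD (n−1); an n = 1 group reports SD 0 with an
explanatory note. Groups are formed upstream by (system, force) — pooling
across forces is rejected.

## State classification

The four categories are defined by qualitative curve shapes; the numeric
rule here is this package's operationalisation. Per run, the last
`tail_window` ns (default 4 ns) is summarised into tail means/SDs of the
two reference series and of the swing angle, and the first `tail_window`
ns gives a head mean for the HA series. Rules are evaluated in priority
order 4 → 3 → 2 → 1:

1. **swing-out (4)**: tail swing ≥ `swingout_min` (25°), or both
   reference tails ≥ `high_rmsd` (5 Å) while fluctuating
   (tail SD > `fluctuation_sd` = 1 Å);
2. **transition (3)**: HA series dropped by ≥ `transition_drop` (3 Å)
   from head to tail **and** the run ends clearly HA-like:
   `tail_LA − tail_HA > convergence_gap`. The second condition is
   deliberately a margin, not a bare sign test: a converging category-2
   run also shows a large HA drop and ends with the two tails equal up
   to noise, so a sign test would flip a coin on it;
3. **convergence (2)**: |tail_LA − tail_HA| ≤ `convergence_gap` (1.5 Å);
4. **stay-LA (1)**: tail_LA ≤ `low_rmsd` (2.5 Å) and tail_HA above it.

If no rule fires, the category with the strongest margin is chosen and
the call is flagged as a fallback; every call carries its evidence
(tail means, gap, drop, swing) so borderline runs are auditable. An
optional IA-reference series only annotates category-3 calls (whether
the run ends closer to the IA than the HA endpoint); it takes no part in
the decision. Whether published classifications summarised tails or
whole runs is not documented anywhere we know of; the tail-window
summary is this package's convention. Category 2 is detected purely as
convergence of the two series — it has no crystal endpoint and the
detection is heuristic by nature.

Default thresholds were calibrated once against the synthetic templates
(9 Å LA↔HA α7 displacement): the stay-LA tail reads √3·σ ≈ 0.9–1.7 Å for
σ = 0.5–1 Å noise (well under 2.5 Å), the midpoint drift leaves a ~0 Å
gap (well under 1.5 Å), the transition leaves an ~8 Å gap and a ~5 Å
drop, and drawn swings of 30–45° clear 25° by ≥ 5°.

## Synthetic data: what it emulates, and what it does not

Templates are **geometric scaffolds**: a poly-alanine-like chain of 190
residues (author numbers 130–319) with named landmark residues carrying
real Cβ and side-chain-oxygen pseudo-atoms, a HETATM Ca²⁺ ion, and an
optional ligand residue (Glu/Asp carboxylate) on a second chain. They
are not homology models and have no chemistry; they exist so every
geometric quantity is controlled exactly:

* the LA template realises the crystallographic sphere pattern
  (S139/S141/D239 ≤ 3.5 Å; D137/T206 beyond), the activated states swap
  S141 out and D137/T206 in;
* the HA template translates the mobile α7 unit (residues 292–305,
  including the zipper Phe just N-terminal of the helix) rigidly by 9 Å
  axially — within the 8–11 Å per-residue range such transitions show —
  so the configured displacement *is* the core-aligned segment RMSD, and
  the zipper Cβ pairs close from exactly 10 Å to exactly 5 Å as a
  consequence; the IA template sits at half displacement (so a stay-LA
  run reads ≈ 4.5 Å against IA, between the LA and HA readings);
* equilibration runs drive that unit with a smoothstep schedule over the
  first 60% of frames: category 1 holds, 2 drifts to the midpoint, 3
  completes the displacement and translates the ion inward by a drawn
  2.1–2.8 Å, 4 rotates the helix about its N-terminal Cα by a drawn
  30–45°; defaults are 100 frames × 0.1 ns (a 10 ns run);
* noise is isotropic Gaussian per atom per frame, independent across
  frames (σ default 0.5 Å). **No kinetics is claimed**: there is no
  force field, no solvent, no correlated motion, no realistic
  fluctuation spectrum. Passing tests show the *analysis* recovers known
  geometry under noise — not that the generator resembles real MD beyond
  the geometric signatures listed above;
* separation traces sit at a bound baseline (2.2 Å) and jump to the
  threshold at the drawn crossing time, then ramp at 20 Å/ns, with
  optional sub-dwell rebinding excursions and optional censoring. The
  recovered lifetime is exact by construction at σ = 0 when the crossing
  time lies on the frame grid.

One seeded generator per call; the seed is recorded in every truth
record, and identical (spec, seed) reproduce byte-identical PDB output.

## Problem sizes and determinism

Tests and the acceptance script run the classifier batches at 40 runs
per noise level (10 per category) of 100 frames × ~960 atoms, the
lifetime oracle at 1000 random traces, and the rotation-grid
superposition oracle at a 2° z-y-z Euler grid (~2.9 M rotations,
evaluated as a single trace inner product per rotation) — sizes chosen
so the whole suite completes in a few minutes on one CPU while keeping
every statistical check meaningfully powered. CSV outputs use fixed
float formatting and no timestamps, so reruns of either workflow on the
same config and inputs are byte-identical.

## Known limitations

* The classifier thresholds are calibrated to the synthetic geometry;
  real systems with a different LA↔HA displacement will need rescaled
  `convergence_gap`/`transition_drop` (exposed in config).
* Correspondence matching cannot bridge renumbered references; residues
  must share author numbering across topology and references.
* mmCIF, XTC/TRR and PSF inputs are out of scope (PDB and DCD only), as
  are flexible/weighted fitting, Markov-state modelling, Bell-type
  force–lifetime fits and any energetic analysis.
* Mac-1 preset entries beyond the residues fixed by the structural
  literature (the α7 segment bounds and core ranges) are offset-mapped
  from LFA-1 and should be overridden per deposition.
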