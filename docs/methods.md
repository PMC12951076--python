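# Methods

This note records the statistical model implemented by `hybridsp`, the
defaults and numerical choices behind it, what the synthetic generator
does and does not emulate, and the known limitations.

## Pair-distribution construction

Contacts between ligand and receptor heavy atoms are histogrammed per
(ligand type, protein type) pair on the half-open range [2, 6) Å in
0.2 Å bins (20 bins). For each pair the local density divides the bin
count by the spherical shell volume 4π r_k² dr evaluated at the **bin
midpoint** r_k = r₀ + (k + ½)dr; the bulk density divides the pair's
total count by the full shell volume (4π/3)(r_c³ − r₀³). The ratio
gives the pair distribution g_ij(r); the reference state g(r) is the
unweighted mean of g_ij(r) over included pairs, and the potential is
ΔW_ij(r) = −ln[g_ij(r)/g(r)] in k_BT units (the thermal prefactor is
set to 1 throughout; scores are relative, not absolute free energies).

Numerical choices:

* **Bin assignment** uses `numpy.digitize` on exact `linspace` edges
  rather than `floor((d − r₀)/dr)`: with binary floats the latter
  misplaces exact edge distances (e.g. d = 3.0 lands in bin 4 instead
  of 5), while digitize keeps every edge in the bin it opens.
* **Reference average over included pairs only.** A pair enters the
  reference mean (and receives a nonzero potential) only when its total
  raw count reaches `min_pair_total` (default 1). Averaging over the
  full 23 × 100 grid would let never-observed pairs drag the reference
  to zero and leave g undefined; sparse pairs score 0 instead.
* **Zero counts.** An optional additive pseudocount α (default 0)
  smooths empty bins; independently, energies are clipped to
  ±`cap` = 10 k_BT so tables are finite everywhere. Bins where the
  reference itself vanishes are reported and set to +cap.
* **Sub-r₀ contacts** are not histogrammed (reported as clashes). At
  scoring time a clash is charged the pair's innermost-bin value by
  default — repulsive in trained tables — or a configurable constant.
* Weighted counts are kept real-valued; nothing is rounded.

## Affinity weighting

With affinities in pK units (−log₁₀ of Kd/Ki in molar), each complex's
contacts carry weight p = exp((A − A_mean)/A_mean), A_mean being the
training-set mean. The weight is 1 at the mean, strictly increasing in
A, and positive everywhere; a complex at twice the mean affinity counts
e ≈ 2.718 times. Weighted training requires every manifest entry to
carry an affinity; the trained table records A_mean in its provenance.

## Atom taxonomies

* **Ligand (23 Sybyl labels).** C.1, C.2, C.3, C.ar; N.1, N.2, N.3,
  N.4, N.ar, N.am, N.pl3; O.2, O.3, O.co2; S.2, S.3, S.o, S.o2; P.3;
  F, Cl, Br, I. Mol2 types are taken verbatim; types outside the list
  map through a shipped fallback table (e.g. C.cat → C.2, O.spc → O.3),
  then by element (C → C.3, N → N.3, …), with C.3 as the final generic
  fallback so typing is total. SDF ligands get types inferred from
  element, bond orders and aromatic flags (carboxylate oxygens are
  recognized from a carbon bearing two oxygens with a double/aromatic
  C–O bond; amide nitrogens from an adjacent carbonyl).
* **Protein, residue-dependent (100 labels).** Each non-glycine
  standard residue owns five slots: BB1 = {N, CA}, BB2 = {C, O}, and
  SC1–SC3 formed by splitting the side-chain heavy atoms, ordered by
  bond distance from CA (Greek remoteness letter), into three
  contiguous near-equal groups (`numpy.array_split` semantics; short
  side chains fill leading slots). Glycine's four atoms are individual
  labels. Everything else — metals, halogens, cofactors, non-standard
  residues, terminal OXT — is UNDEF. 19×5 + 4 + 1 = 100. The grouping
  beyond the slot counts is this package's choice; the topology table
  is shipped as editable TSV data.
* **Protein, Sybyl-style.** A fixed per-residue lookup (backbone
  N → N.am, CA → C.3, C → C.2, O → O.2; side chains per a shipped TSV)
  supports classical atom–atom potentials; non-standard atoms fall back
  by element, then UNDEF.

## Orientation-dependent potential

Residue frames are right-handed orthonormal triads: origin at the first
anchor, x̂ along anchor1→anchor2, ẑ normal to the anchor plane. The
default catalogue has a backbone frame (N, CA, C) for all 20 residues
and a CB-first side-chain frame for the 16 residues with ≥3 side-chain
heavy atoms. Ligand atoms within [2, 6) Å of a frame origin are binned
in (r, cos θ, φ) with dr = 0.5 Å, 6 cos θ bins and 8 φ bins; a pole
(atom on the ẑ axis) takes φ = 0 by convention. Derivation mirrors the
distance case with the volume element r² dr d(cos θ) dφ and a
per-cell reference averaged over included (ligand type, frame) pairs.
These bin counts and anchor choices are package defaults, exposed as
configuration; they were fixed before any benchmark-style evaluation
and are not tuned.

## Hybrid combination

The hybrid score is a plain weighted sum of component energies — no
per-component standardization is applied by default, matching the
combination's definition; components declared "higher is better" are
negated at load so lower is uniformly better. Presets over the
(atom–residue weighted, atom–atom, orientation) slots: dk = (0.4, 0.5,
0.1), scr = (0.6, 0.2, 0.2), bl = (0.5, 0.3, 0.2). External potentials
(e.g. published atom–atom or backbone-orientation grids) participate
via the text table format only; no binary compatibility is attempted.

## Evaluation conventions

* **RMSD** is computed over corresponding heavy atoms without
  superposition (poses share the receptor frame) and without
  graph-symmetry correction — a documented limitation for symmetric
  ligands.
* **Docking success**: a target succeeds when the best pose among the
  `top_n` lowest scores has RMSD < 2 Å; score ties resolve by stable
  input order. With `include_crystal`, the crystal joins as a zero-RMSD
  candidate; if unscored it inherits the best pose score and wins ties.
* **EF** uses a ceiling top-set size: EF = (hits/⌈fN⌉)/(actives/N).
* **AUROC** is the midrank Mann–Whitney statistic: the probability that
  a random active scores lower (better) than a random decoy, ties at ½.
* **Interaction detection** thresholds (all configurable): hydrogen
  bond N/O···N/O ≤ 3.5 Å; weak hydrogen bond C···O/N ≤ 3.6 Å;
  hydrophobic C···C ≤ 4.0 Å between nonpolar carbons; salt bridge
  charged-N···carboxylate-O ≤ 4.0 Å; π–π centroid ≤ 5.5 Å with
  interplane angle ≤ 30° or in [60°, 90°]; cation–π ≤ 6.0 Å; halogen
  bond X···O/N ≤ 3.5 Å with C–X···A angle ≥ 140°. These are
  conventional values; donor/acceptor/nonpolar/charged assignments per
  residue are fixed tables in the module. A record's role describes the
  receptor atom (the consensus analysis asks which receptor atoms do
  the same job across compounds); ring interactions are attributed to
  the ring's anchor atom (CG) to keep one record per ring. Without
  ligand connectivity, ring-dependent types are skipped with a warning.
  Amide stacking and multipolar halogen geometries are out of scope.
* **Consensus**: a (receptor atom, type, role) triple counts once iff
  present in the records of all five top-scored complexes of a target.

## Synthetic generator

The generator plants, per selected type pair, a Gaussian well
W*(r) = −depth·exp(−(r − c)²/2σ²) with center c ~ U(2.5, 5.0) Å, depth
~ U(0.5, 1.5) k_BT, σ = 0.5 Å, on the standard 20-bin grid. Pocket
atoms are placed at distances drawn from the binned Boltzmann density
p_k ∝ r_k² exp(−W*(r_k)) dr — inverse-transform over bins, uniform
within a bin — in independent random directions around a single ligand
probe atom at the origin. This makes the sampled histogram an exact
multinomial draw of the model being recovered, which is the point:
recovery tests then measure pure counting noise. Defaults: 200
complexes, 24 pseudo-residues per pocket (8 each GLY/ALA/SER, chosen so
every pair-bin's expected occupancy stays ≳10 and log-ratio errors
remain in the Poisson regime), single-atom C.3 ligand, affinities
~ U(2, 11) pK. Pseudo-residues carry real residue names and complete
backbone triples so typing and frame construction run the production
paths.

What the generator does **not** emulate: covalent geometry, sterics,
multi-atom ligands with correlated contacts, residue-packing
correlations, experimental-affinity noise, or crystallographic
artifacts (altlocs, partial occupancy). Passing recovery tests
therefore demonstrates correctness of the statistical machinery — not
predictive performance on real structures, which depends on training
data the package's user supplies.

Expected recovery tolerances are set from counting statistics: with
minimum expected bin occupancies around 10–25 at 200 complexes, the
worst |ΔW| error across ~220 pair-bins is bounded near 0.8 k_BT, and
quadrupling the ensemble halves the statistical error (tests use 0.8 at
n = 200 and 0.5 at n = 800 with a fixed seed). The analytic route —
deriving from the exact expected histogram — recovers the
reference-adjusted planted profiles to ≤ 1e−6.

## Table serialization

Potential tables are UTF-8/LF TSV with `# key=value` headers (schemes,
grid, clash policy, provenance) and one row per nonzero entry, energies
at 6 significant digits; absent rows mean ΔW = 0. Serialization is
deterministic and read→write round-trips are byte-identical, so trained
tables can be diffed and version-controlled.

## Degenerate inputs and edge behavior

Empty manifests, histograms without counts, all-sparse histograms,
weighted training with missing affinities, and atom-count mismatches in
RMSD all raise; collinear frame anchors are skipped with a warning
during accumulation and raise when requested directly. Typing never
raises: unknown atoms land on documented fallbacks. Structures keep
only heavy atoms; altlocs resolve to highest occupancy (ties: first
encountered); waters are dropped; first NMR model only; metals and
cofactors in the pocket are kept as receptor atoms and type as UNDEF.

## Limitations

No pose generation or minimization; no solvation/entropy terms; no
iterative reference refinement; no absolute binding free energies; no
symmetry-corrected RMSD; no pH-dependent protonation in typing.
Benchmark-scale claims require real training and test sets supplied by
the user.
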