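# Methods

`cgfold` is a desk-scale engine for contact-guided ab initio protein
folding: it combines residue–residue contact predictions from several
predictors of unequal reliability, converts the selected contacts into
smooth restraint wells inside a coarse-grained force field, folds the
chain by fragment-assembly replica-exchange Monte Carlo (REMC), and
picks final models by clustering the simulation decoys.  This note
records the model, its parameters, and the design decisions taken where
the design was genuinely open.

## Chain representation

A protein is a Cα trace with fixed virtual bonds.  Bond lengths are
3.8 Å in all generated geometry; the sampler keeps them within
[3.4, 4.2] Å after every accepted move.  Side chains enter only through
a virtual Cβ placed 1.53 Å from Cα, opposite the bisector of the two
flanking virtual bonds and tilted 0.66 rad out of their plane; glycine
and chain termini use Cα itself.  Local state is described by the
pseudo bond angle θ_i (deflection of consecutive bond directions) and
pseudo torsion τ_i (dihedral of four consecutive Cα).  The ideal helix
(rise 1.5 Å/residue, 100°/turn) and strand (rise 3.3 Å/residue, pleat
amplitude set by the bond length) are parametrised once in
`geometry.py` and their θ/τ values derived numerically from that
parametrisation, so the fold generator, the chain initialiser, the
secondary-structure bias and the M4 move all agree exactly on what
"ideal helix" means.  (An earlier symbolic table of ideal angles used a
different sign convention from the measured pseudo-torsions and made
the energy bias fight its own generator; deriving the constants from
the generating geometry removed that class of bug.)

## Contact restraint selection

Each predictor belongs to one of four reliability tiers (very high,
high, medium, low); the shipped tier table routes NeBcon, ResPRE and
DeepPLM to very-high, DeepCov, DeepContact and DNCON2 to high,
MetaPSICOV2 to medium, and GREMLIN, CCMpred and FreeContact to low;
unknown predictors default to medium.  Selection walks the tiers from
most to least reliable with contacts-per-residue quotas
(1.0, 0.8, 0.4, 0.2)·L — 2.4·L in total — admitting candidates in
descending confidence provided the confidence clears the tier cutoff

    min_conf_t(Nf) = base_t · (1 + 1/(1 + Nf/15)),
    base = (0.15, 0.20, 0.25, 0.30)

which roughly doubles the required confidence for alignments with a
very low effective depth (Nf, computed as (1/√L)·Σ_n 1/(1+m_n) with m_n
the number of other rows at ≥80% identity over mutually aligned
columns).  Quota a tier cannot fill cascades to the next tier down, so
the budget degrades gracefully when predictors are missing or
unconfident; an empty selection is valid and the simulation then runs
unguided.  Each selected contact carries the confidence of the record
that selected it; the well depth is that confidence times the contact
term weight.

Consensus ranking (used for reporting and ordering) scores a pair by
Σ tier_weight·confidence over the maps containing it, with tier weights
(1.0, 0.8, 0.6, 0.4) and ties broken toward larger sequence separation.

## Force field

The composite energy is a weighted sum of six terms evaluated on the
Cα/virtual-Cβ geometry:

* **Contact restraints (3G potential), weight w_con = 2.0.**  For each
  selected pair, on the Cβ distance d:
  −U below 8 Å; −(U/2)[1 − sin((d − (8+D)/2)·π/d_b)] on [8, D);
  (U/2)[1 + sin((d − (D+80)/2)·π/(80−D))] on [D, 80]; +U beyond 80 Å,
  with D = 8 + d_b.  The curve is continuous with zero slope at 8, D
  and 80 Å, applies a strong pull between 8 Å and D and a deliberately
  weak one between D and 80 Å (so false positives cannot crush the
  chain), and is flat beyond 80 Å.  The gradient width d_b is 6 Å for
  targets under 100 residues, 12 Å above 200, and bridges linearly in
  between — the minimal monotone interpolation between the stated
  endpoints.  w_con was calibrated on the synthetic fixtures (2.0 gives
  the contact term clear authority over the generic chain terms during
  final packing; 1.0 left the cold replicas dithering between
  half-satisfied packings).
* **Fragment distance profiles, weight w_dp = 3.00** (the re-weighted
  value that lets fragment statistics veto false contacts).  For each
  usable profile, −ln[(h(d)+ε)/(h_max+ε)] on a 0.5 Å-binned histogram
  of Cα distances smoothed with a narrow Gaussian (σ = 0.75 Å), ε=1e−3,
  zero below the first populated bin and above 20 Å.
* **Chain-break penalty, w_ca = 1.0**: (d − 4)² for adjacent Cα beyond
  4 Å (zero below) — fragment replacements can tear the backbone and
  this ramp heals it smoothly.
* **Excluded volume, w_ev = 1.0**: (3.6 − d)² for non-bonded Cα pairs
  (|i−j| ≥ 2) closer than 3.6 Å.
* **Secondary-structure bias, w_ss = 0.5**: 1 − cos(θ − θ_ideal) plus
  1 − cos(τ − τ_ideal) for residues confidently predicted H or E
  (state probability ≥ 0.7).  Raising this weight was tried and made
  packing worse — locking the SSEs too hard starves the topology
  search — so 0.5 stands.
* **Radius-of-gyration confinement, w_rg = 0.2**: quadratic penalty
  outside ±15% of 2.2·L^0.38 Å.  This supplies the unspecific collapse
  pressure that solvation terms provide in a full force field.

The last four terms are generic chain physics, not a reimplementation
of any published force field; they are the minimum a Cα-level engine
needs to fold at all.

Energies are evaluated incrementally during sampling: a move declares
the residues it touched and only the affected interactions are
re-summed (Cβ dependencies widen the affected set by ±1 residue,
pseudo-angle windows by ±2; the radius-of-gyration term is global but
O(L)).  The hot path is a numba-compiled kernel mirroring the numpy
reference implementation; the two paths and the full recomputation are
held to 1e−8 agreement by oracle tests, so the kernel is an
optimisation, never a second model.

## Fragments and distance profiles

The query is threaded gaplessly against a library of coarse structures:
every window of every library structure is scored against every query
position for fragment lengths 1–20 by mean BLOSUM62 substitution score
plus the fraction of matching 3-state secondary-structure labels
(weight 1.0, with library SS assigned geometrically from pseudo-angle
ranges), and the best 200 windows per (position, length) slot are kept.
Library entries with more than 30% global-alignment sequence identity
to the query are removed first (strictly greater than — a structure at
exactly 30% stays).

Distance profiles: for a residue pair (i, j), kept fragments starting
at i and at j that come from the same source structure with the same
register offset vote for the source distance between the residues they
map onto.  Two choices depart from a plain count histogram, both forced
by desk scale and recorded here deliberately:

* votes are weighted by exp(2·(score − slot best)), because against a
  ~50-structure library the top-200 cut keeps a third of *all* windows
  and is not selective by itself;
* profiles are built only for sequence separations 3–8.  With a small
  library of toy folds the placements are register-degenerate at larger
  separations (a helix window matches every helix equally well), and
  measured against held-out targets the longer-separation histograms
  peak away from the true distance more often than at it.  Short-range
  geometry is locally determined and recurrent, which is exactly the
  regime the fragment evidence is good for.

A profile becomes a restraint only when its modal bin centre lies below
9 Å.

## REMC sampler

Replicas (desk default 8; production preset 40) run at a geometric
temperature ladder, desk default T ∈ [0.1, 2.5] in energy units —
calibrated on the fixtures so that breaking one satisfied contact is
rare at the cold end and routine at the hot end.  Each cycle every
replica attempts round(30·√L) moves under Metropolis acceptance, then
adjacent replicas swap conformations with probability
min(1, exp((1/T_k − 1/T_{k+1})(E_k − E_{k+1}))), alternating odd/even
pairings per cycle (desk default 100 cycles; production 500, and five
independent simulations instead of one).

Eleven move types in three levels:

* residue level — M1 torsion pivot (rotate downstream of a bond; the
  N→C propagation convention is fixed for reproducibility), M2
  single-Cα displacement, M3 bend about a random axis through one Cα,
  M4 reset of one residue's θ/τ to the ideal values for its predicted
  state;
* segmental — M5 fragment substitution (a library fragment is
  superposed onto the current window by least squares and swapped in),
  M6 crankshaft rotation between anchors (spans 2–14), M7 rigid shift
  of a short segment, M8 a three-bond torsion wiggle;
* topology — M9 terminal-tail hinge rotation, M10 rigid translation and
  M11 rigid axial rotation of one secondary-structure element.

Moves that cannot preserve bond bounds analytically (M2, M5, M7, M10,
M11) close the chain by rejection: a proposal that would leave any
adjacent Cα distance outside [3.4, 4.2] Å is discarded before energy
evaluation.  Level frequencies are (0.55, 0.30, 0.15)
residue/segmental/topology at the cold end, annealing to
(0.40, 0.35, 0.25) at the hot end, and fragment substitution is given
3× the weight of its level-mates.  Step sizes scale with √(T/T_mid),
clipped to [0.4, 2.5]: cold replicas refine, hot replicas roam.  Both
the step scaling and the cold-end level mix came out of fixture
calibration — without them the cold replicas could not finish packing
within a desk-scale cycle budget.

Each replica draws from its own generator spawned from the master seed,
so changing the replica count does not silently shift the streams, and
a (config, seed) pair reproduces trajectories bitwise.  Snapshots are
taken from the cold half of the ladder at a configurable stride, with
the snapshot energy recomputed in full (this also re-anchors the
incrementally tracked energy).  The per-cycle log records the coldest
replica's energy and restraint satisfaction rate; unguided runs can be
asked to monitor a reference restraint set for the same log.

## Model selection

Decoys pooled from the cold replicas (after discarding the first 30%
of cycles as burn-in) are clustered by iterative densest-ball search on
pairwise Cα RMSD: the decoy with the most neighbours within the cutoff
seeds a cluster, members are removed, and the process repeats for up to
five clusters.  The cutoff starts at 3.5 Å and auto-scales within
[2.5, 8] Å until the largest cluster holds 10–70% of the decoys.
Clusters are ranked by size (the largest basin proxies the lowest free
energy), ties by lower mean energy; each cluster's model is the member
minimising the summed RMSD to its co-members.

## Evaluation

Contact precision is the fraction of the top-k most confident
predictions in a separation class (short 6–11, medium 12–23, long ≥24,
following assessment convention) that are native, nativeness meaning
virtual-Cβ distance under 8 Å.  Satisfaction rate is the fraction of
selected restraints realised under 8 Å in a model.  Cα RMSD uses the
Kabsch superposition; the test suite cross-checks it against a
quaternion-method oracle.  TM-score is maximised over iteratively
refined superpositions grown from window seeds (several lengths, every
start), normalised by the common length with
d0 = 1.24·(L−15)^(1/3) − 1.8 floored at 0.5; the suite holds it to
1e−3 agreement with an exhaustive-seed scorer.

## Synthetic data: what it emulates and what it does not

The fixture generator builds ideal-geometry α/β/αβ folds (helix
bundles, strand sheets and sandwiches, mixed packings) with exact
3.8 Å bonds, loops laid on circular arcs chosen to bulge away from the
fold, and sequences drawn from secondary-structure-biased alphabets.
Contact corruption is exact-count: a map requested at precision p with
n predictions contains round(p·n) native pairs, false pairs reuse the
native separation distribution (so selection cannot cheat on
separation), and confidences are laid out so the fraction of true
contacts is non-increasing from the top confidence decile down —
calibration is a construction, not a sampling hope.  Synthetic MSAs
control Nf through 80%-identity cluster counts and are verified by
recomputation.  The fragment source library mixes fixed templates with
randomly drawn topologies, varying SSE lengths, loop lengths and
packing spacing.

Limits to keep in mind when reading passing tests: toy sequences carry
no real sequence→structure signal, so threading selectivity comes from
secondary structure and register only; loop geometry is deterministic
per topology rather than sequence-dependent; contact maps of flat or
layered β folds genuinely underdetermine their global shape at the
8 Å/Cβ definition, which caps attainable model quality on those
targets exactly as low contact information does for real β proteins;
and a contact map is mirror-symmetric, so chirality is carried only by
the helix bias and fragments.  Desk-scale runs (8 replicas × 100
cycles × 30·√L moves) are two orders of magnitude smaller than
production folding budgets; quantitative fold quality here calibrates
the machinery, not the method's ceiling.

## Numerical choices

* Restraint depths store raw confidences; the single knob w_con scales
  the whole term (no double scaling between selection and energy).
* Profile tables cap their support at 20 Å and treat bins below the
  first populated one as unknown (zero), not forbidden.
* Clustering tie-breaks and the centroid rule are deterministic, so
  model ranking is reproducible given the decoy set.
* Trajectory statistics (satisfaction-vs-cycle correlations) are
  computed on the post-burn-in window (cycle > 30): the initial
  collapse raises any contact count, guided or not, and carries no
  information about guidance.
* Seeds: every stochastic component takes an explicit seed; fixture
  generators are bit-reproducible from (spec, seed).

One further caveat on the fragment channel: because toy sequences are
register-uninformative, the distance-profile term inherits noise that
the production weight (w_dp = 3.00, kept as the shipped default) was
never tuned for; on synthetic panels the fragment *moves* help while
the profile *energy* can hurt, so ablating the whole fragment module
does not reproduce the degradation expected of a production system.
Users folding synthetic targets who care only about topology recovery
can set w_dp lower; the default stays at the production value because
this package's purpose is to exercise the production design.
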