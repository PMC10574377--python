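# Methods

## The model

A *graph machine* estimates the refractive index n (589 nm, 20–30 °C) of a
liquid organic compound directly from its SMILES.  The molecule's
hydrogen-suppressed graph is turned into a rooted acyclic computation
graph; one *shared* node function — a single-hidden-layer perceptron with
tanh hidden neurons and a linear output — is instantiated at every heavy
atom, receives the scalar outputs of the node's children in fixed,
canonically ordered input slots (zero-padded) plus indicator inputs for
the node's labels, and passes its scalar output to its parent.  The root
node's output is the estimate.  Because a single parameter vector θ is
shared by all nodes of all molecules, the model's complexity equals that
of the node function, and the prediction depends only on the labeled 2D
structure.

Node labels are:

* the element symbol (one-hot over a configurable alphabet; the default
  alphabet covers B, C, N, O, F, Si, P, S, Cl, Ti, Ge, Se, Br, Sn, I —
  up to 16 atom types counting hydrogen, which is never a node);
* the degree D_k = sum of kekulized bond orders to heavy neighbours
  (an olefinic CHCl carbon has D3: one single bond + one double bond);
  aromatic systems are kekulized first;
* stereochemical labels: a stereo double bond contributes iso labels to
  its two sp² atoms — {iso1, iso1} for E, {iso1, iso2} for Z — and
  tetrahedral stereocentres carry chi labels encoding *relative*
  configuration: the centre of lowest canonical rank is the reference
  (chi1) and every other centre gets chi1 if its CIP descriptor matches
  the reference ("like") and chi2 otherwise.  Mirror images therefore
  encode identically while diastereomers differ.  A molecule with exactly
  one tetrahedral stereocentre and no stereo double bond is a potential
  enantiomer, so its chi label is discarded before encoding.

### Cycle opening and the root

Rings are opened by removing one edge per independent cycle; degree
labels are *not* decremented, so the two cut atoms advertise the
disconnection (their degree exceeds their tree neighbour count).  Two
choices are not fixed by the modeling idea itself and are therefore
explicit, documented conventions here:

* **Root.**  By default the root is a node of minimal eccentricity (graph
  centre), ties broken by lowest RDKit canonical rank (computed without
  chirality so it is enantiomer-invariant), then atom index.  For
  2,3-dimethyloxirane this roots the DAG at the oxygen.  The root can be
  overridden with atom map 1 in the SMILES (`[C:1]1=NN=CC=C1`), which
  matters in practice: the root's atom label is the last one applied.
* **Ring edge.**  Cycles (networkx `cycle_basis`, recomputed after every
  removal so exactly the cyclomatic number of edges is removed) lose the
  edge whose endpoints lie jointly farthest from the root, ties broken by
  canonical rank.  This keeps the root's neighbourhood intact.

Children at each node are ordered by a canonical subtree key (atom type,
degree, labels, recursively the children's keys), which makes evaluation
deterministic and independent of SMILES atom numbering.

### Parameter layout

With F trainable input lines (child slots + atom one-hot + degree one-hot
+ four stereo indicators), the parameter vector is
`[W (H×F), hidden biases (H), output weights (H), output bias]`, i.e.
H·(F+1) + H + 1 parameters for H hidden neurons and F+1 for the
degenerate linear node function (H = 0).  The bias units of the model's
usual pictorial convention are realized as the explicit bias parameters;
this keeps the linear case full-rank (a single intercept), which the
closed-form training and leave-one-out oracles rely on.  Elements outside
the alphabet leave the atom one-hot all-zero, so their label weights
contribute nothing (with a warning), and degree labels above the
configured maximum raise.

## Training

The cost is the unregularized sum of squared errors
J(θ) = Σ (y_i − g_i(θ))²; the fit summary is
RMSTE = √(J/N_T).  Minimization is a Levenberg–Marquardt loop on the
shared parameters: solve (JᵀJ + λI)δ = −Jᵀr, multiply λ by 10 on a
rejected step and divide by 10 on acceptance, so accepted steps never
increase J.  Defaults (declared, not derived from any reference): initial
λ = 1e−3, stop when the cost-gradient infinity norm < 1e−6 or the
relative cost decrease < 1e−9 or after 500 iterations.  Exactly singular
normal matrices (weight-sharing symmetries) are handled by the damping
itself plus a least-squares fallback.  Initial parameters are uniform on
[−0.3, 0.3], a standard scale for tanh units; training is repeated from
many seeded initializations (default 100; the package derives per-start
substreams so start i is reproducible regardless of the total).

Targets are not normalized — refractive indices are already O(1).
Overfitting is controlled by model selection, not by regularization or
early stopping.

For speed, all molecules of a training set are flattened into one
level-indexed node array so each forward/Jacobian pass is a handful of
matrix operations (`GraphBatch`); the per-graph reference implementation
is kept and the test suite cross-checks the two paths.

## Model selection: virtual leave-one-out

Exact leave-one-out is N_T retrainings; instead the model is linearized
at the trained θ_m.  With Z the Jacobian of model outputs w.r.t. θ, the
hat-matrix diagonal h_i (computed from a rank-revealing SVD of Z, so
parameter redundancy is harmless) inflates each residual into a
first-order leave-one-out residual r_i/(1−h_i), and

    VLOO = √( mean( (r_i/(1−h_i))² ) ) ≥ RMSTE.

For a model linear in θ this is exactly the PRESS statistic; the test
suite verifies the identity against brute-force retraining to 1e−8.
1−h_i is clamped at 1e−6 and clamped examples are reported; a model whose
examples all clamp has a meaningless score (warned).  Leverages near 1
mean the linearization interpolates that example — such models receive a
huge VLOO and are naturally discarded by the selection step below.

The scan protocol: for each candidate complexity (number of hidden
neurons), run `repetitions` independent rounds of `n_starts` trainings;
in each round keep the k models of smallest VLOO; report the means of
RMSTE and VLOO over the kept models, and the mean extreme deviations
(MIN/MAX) on the training set.  The recommended complexity is the most
parsimonious one whose mean VLOO is within 5e−4 of the observed floor —
the floor tolerance operationalizes "the score hardly decreases beyond
this size".  Ensemble prediction averages the kept models within each
round and then across rounds; predictions are reported to 3 decimals.

## Homologous series

Within a homologous series (repeat unit CH₂, CF₂, Si(CH₃)₂O, …),
additivity of polarizability and molar volume gives

    n(N) = √( (n_repeat²·N + B) / (N + C) ),

with n_repeat the index of the infinite polymer of the repeat unit and
B/C = n² of the initial member; n(N) is monotone, increasing exactly when
n_repeat² > B/C, and constant when B = n_repeat²·C.  The fitter minimizes
least squares on n (not n²) — the closed form is exactly linearizable in
(n_repeat², B, C), which provides the initial values, followed by a
bounded nonlinear refinement.  With a CH₂ repeat unit n_repeat can be
fixed to the polyethylene value 1.476.  Points are weighted equally.

## Curation rules

* RI values are rounded to 3 decimals on ingestion (typical measurement
  scatter exceeds 0.001).
* Records with a known measurement temperature outside 20–30 °C are
  dropped; records without a temperature are kept (catalog sources often
  omit it).
* Duplicate key = canonical serialization of the stripped, labeled DAG,
  so enantiomers and their racemate collide while diastereomers do not.
  The survivor prefers a record whose input SMILES carried stereo labels
  (an enantiomer over the racemate); remaining ties go to the
  lexicographically smallest SMILES — a deterministic local rule standing
  in for set-balancing choices that cannot be reproduced record-wise.
* A record with no stereo labels whose skeleton also occurs with labels
  is an unspecified cis/trans (or E/Z) *mixture* and is dropped; a
  mixture standing alone is kept, unlabeled.
* After training, records whose |prediction − measurement| exceeds 0.020
  are flagged for manual literature verification; nothing is modified
  automatically.

## Synthetic data: what it emulates, and what it does not

Quantitative behavior is exercised on teacher–student data: a planted
graph machine labels randomly generated molecules; Gaussian noise of
sd 0.002 (the order of real measurement scatter) is added; values are
affinely mapped into the empirical RI window 1.296–1.687.  The molecule
generator grows carbon-backbone trees (2–12 heavy atoms) over the
alphabet C, N, O, F, S, Cl with valence-respecting bond orders,
heteroatoms bonded to carbon only, ring closure with probability 0.25
and stereo assignment (carbon tetrahedral centres, double-bond E/Z) with
probability 0.5.  These choices imitate two statistical properties of
curated liquid catalogs that the method's selection machinery depends
on: every label indicator is carried by many molecules, and structures
come in families rather than as one-off exotica.  The generator does not
emulate chemical class balance, tautomerism, aromatic heterocycle
diversity, or measurement-temperature structure — so passing tests show
that the machinery (encoding, training, selection) is correct, not that
any particular accuracy holds on real catalog data.

The affine window calibration is recorded on the teacher because a
scaled-and-shifted graph machine is *not* itself a graph machine (the
zero-padding of empty child slots breaks the reparameterization), so
exact-recovery checks (noise 0 → RMSTE < 1e−4) run with the calibration
disabled, where the teacher is a member of the student's family.  With
the calibration on, students still fit to the noise level in practice.

### Problem sizes used by the checks

* Recovery: 200 molecules, 4-hidden-neuron teacher, noise sd 0.002, 30
  starts; the best student reaches RMSTE ≤ 0.003.
* Complexity scan: 600 molecules for the {2, 4, 8} scan.  At 200
  molecules the 8-neuron model (185 parameters) sits at N/P ≈ 1.1, where
  the VLOO linearization degenerates (hat diagonal ≈ 1 for many
  examples) for every start; at 600 the ratio (≈ 3.2) is comparable to
  the regime the selection protocol is meant for, and the expected
  signature appears — RMSTE decreasing, VLOO floor at the planted size,
  parsimonious recommendation.
* PRESS identity: 30 single-atom molecules (the linear regime of the
  model family), each atom type appearing several times so leave-one-out
  predictions stay unique under rank deficiency.

## Known limitations

* The default root and ring-opening conventions are exactly that —
  conventions.  Predictions can depend on them (the root-override hook
  exists precisely because the root's atom label matters); models are
  only comparable when encoded under the same conventions.
* chi labels encode relative configuration through CIP "like/unlike"
  descriptors, which is coarser than full relative stereochemistry for
  exotic stereo topologies (atropisomerism, planar chirality are not
  handled at all).
* The node function caps children at `n_child_slots` (default 4,
  configurable to 6); molecules with higher-degree centres than slots
  raise rather than silently truncating.
* VLOO is a first-order estimate: near interpolation (N_T close to the
  parameter count) it degenerates, which the leverage clamp reports
  rather than hides.
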