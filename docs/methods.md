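# Methods

This note records the models, conventions and numerical choices behind
`ubrbox`, and what the synthetic tests do and do not demonstrate.

## Structure handling

Structures are read with gemmi and flattened to a list of atom records
with author residue numbering (the numbering used throughout the
UBR4 literature, e.g. Phe1671, Lys1708).  Alternate conformations are
collapsed to the highest-occupancy conformer, ties resolved toward
altloc `A`, so all downstream geometry sees a single coordinate per
atom.  Coordinates are Cartesian ångströms; every cutoff is a
heavy-atom distance — the target crystal structures (1.65–2.18 Å) carry
no reliable hydrogens, and we prefer an honest distance-only criterion
to a modelled-hydrogen one.

**Symmetry expansion.**  Crystal-contact analysis (the N-terminal
degron of one molecule binding the pocket of a lattice neighbour)
requires symmetry mates.  Every space-group operator, combined with the
integer lattice translations whose images can fall within the search
radius (per-axis fractional bounding boxes inflated by the radius plus
a 0.05 safety pad), is applied to the asymmetric unit; an image is kept
when any of its atoms lies within the radius (default 5.0 Å) of an
original atom.  Copies are flagged and labelled
`chain~operator[+i+j+k]`, which makes contact reports reproducible and
lets every copy be re-derived from the stored operators.  Whole images
are kept rather than clipped atom subsets so that residues at the
interface remain complete.

## Pi-interaction geometry

Ring planes are least-squares fits: the normal is the smallest
principal axis of the centred ring atoms (SVD), and the planarity RMS
is the out-of-plane root-mean-square deviation.  The normal's sign
follows a right-handed convention over the first two ring atoms; the
sign never matters because γ is folded into [0°, 90°]
(γ = arccos |n₁·n₂|).  PHE/TYR contribute their six-membered ring, HIS
its imidazole, and TRP both rings independently (no fused-ring
centroid).  A ring with any member atom missing is skipped with a
warning instead of biasing the centroid.

**Classification bands.**  The literature reports class instances, not
boundaries, so the bands are a package choice, configurable at every
entry point: parallel [0°, 30°), intermediate [30°, 50°), T-shaped
[50°, 90°], left-closed so boundary values classify deterministically.
These bands place the observed UBR4 pocket geometries (44.9° and 47.6°
intermediate; 50.8° and 77.6° T-shaped) in their published classes.
The detection window on R_cen defaults to [3.0, 7.0] Å — deliberately
wider than the canonical 4.7–6.5 Å stacking range, which we treat as a
report annotation rather than a filter, so near-boundary contacts are
not silently dropped.

**Cation–pi.**  Cation centres are Lys NZ and the mean of the Arg
NE/CZ/NH1/NH2 guanidinium atoms.  A contact is reported when the
centre lies within 6.0 Å of a ring centroid with the centroid→cation
vector within 60° of the ring normal; both criteria are configurable.

## Coordination spheres, hydrogen bonds, waters

Metal donors are N/O/S atoms within 3.0 Å of the metal (Zn–S ≈ 2.3 Å,
Zn–N/O ≈ 2.1 Å; 3.0 Å admits the first shell and excludes the second),
sorted by distance.  The pattern string counts unique coordinating
*residues* by class — `C` (Cys), `H` (His), `X` (anything else,
including waters) — in fixed C, H, X order, omitting zero classes, so
`C2H2`, `C4` and `C3X1` are canonical.  Donor-free sites report `C0H0`
with a warning.  Hydrogen bonds are heavy-atom N/O/S pairs at
1.8–3.5 Å across different residues; without hydrogens no angle term is
applied, a documented limitation that slightly over-counts.  The
pocket-water census counts unique water oxygens within a configurable
cutoff (default 4.0 Å) of an anchor selection; the count near a
specific side chain is sensitive to this cutoff, which is therefore
always exposed and recorded in the report provenance.

## Superposition

Kabsch superposition is computed in-package via SVD of the covariance
of the centred coordinate pairs, with the determinant correction that
excludes reflections; it requires ≥ 3 non-collinear pairs.  Structure
alignment pairs Cα atoms through a global sequence alignment of the
chain sequences and superposes matched pairs.  Optional trimming
iteratively discards pairs deviating by more than 2.0 × RMSD and
refits until stable (never below 3 pairs) — comparable to the
outlier-rejecting behaviour of interactive alignment commands.
Because published inter-domain RMSD values depend on the (usually
unstated) pairing and rejection settings of the software that produced
them, cross-package comparisons here are *ordering* checks (which pair
of domains is more divergent), not numerical equality checks.

## Sequence alignment and subfamily typing

The pairwise core is an affine-gap Needleman–Wunsch/Gotoh with BLOSUM62
(gap open 10, extend 0.5), implemented in-package and cross-checked in
the tests against Biopython's independent global aligner.  The
progressive MSA aligns profiles column-against-column (sum-of-pairs
scores, gaps scoring 0) along a UPGMA guide tree built from pairwise
percent-identity distances; ties and input order cannot change the
result because sequences are processed in sorted-id order.  Subfamily
typing reads the single alignment column matched to the reference
Zn2-coordinating position: H ⇒ subfamily 1 (UBR1-like), C ⇒ subfamily
2 (UBR4-like), anything else unclassified.

The packaged seven-sequence FASTA is a **synthetic stand-in** (so named
in its filename and loader docstring): it reproduces the features the
classifier relies on — conserved Zn1 C2H2 columns in all seven
sequences, His at the Zn2 column in UBR1–3 and Cys in UBR4–7, UBR4
numbered 1660–1729 with its functionally named residues at the right
offsets — with realistic (~25%) divergence and small loop indels, but
it is not the set of real database sequences.  Tests passing on it show
the alignment and typing machinery is correct, not that any particular
database sequence classifies one way or the other.

## ITC model and fitting

The single-site isotherm uses site concentration S = n·[M] and solves
the mass-action quadratic for the bound complex.  Dilution follows the
constant-volume displacement model: each injection of volume dV
displaces the fraction dV/V₀ of the mixed cell contents (macromolecule,
ligand and complex alike), standard for overfilled cells, which makes
simulated heats bit-reproducible from a seed.  The heat of injection i
is V₀·ΔH·([MX]ᵢ − [MX]ᵢ₋₁(1 − dV/V₀)) + baseline, in µcal.

Fitting is Levenberg–Marquardt (lmfit) on (n, log₁₀K_D, ΔH, baseline),
multi-started across K_D decades 10⁻⁷–10⁻² M with the lowest residual
sum kept; K_D is fitted on a log scale to keep it positive and its
standard error is transformed back.  The first injection is excluded by
default (the usual partial-fill artefact).  Identifiability is governed
by the Wiseman c-value c = n·[M]/K_D: fits with c outside [0.1, 1000]
are flagged low-confidence.  **For weak binders measured at c < 1 the
stoichiometry is held fixed at the known value** (here 1:1 peptide
binding) — with n free at c ≈ 0.4 the recovered K_D carries a
systematic upward bias of order 10% because n and K_D are strongly
correlated, while fixed-n fits are near-unbiased; this is the standard
low-c practice and the `fix_n` argument keeps the choice explicit at
the call site.  Flat series return an `identifiable=False` fit rather
than raising; non-convergence is always flagged.

**Simulation ground truths.**  The recovery studies simulate the two
reported measurement conditions: K_D = 385 µM under the
high-concentration protocol (1400 µL cell at 0.225 mM, 4.5 mM syringe)
and K_D = 18.3 µM under the standard protocol (0.05 mM cell, 1 mM
syringe), both with 5 µL injections (60 from a 300 µL syringe) and 2%
proportional Gaussian heat noise.  The published work reports only K_D,
not ΔH, so the simulations use −3.0 kcal/mol (weak binder) and
−8.0 kcal/mol (tight binder), typical peptide–domain enthalpies; this
choice affects signal-to-noise, not the ground truth being recovered.
Recovery is summarised by the median fitted K_D over 50 seeded
replicates.  Gaussian, independent injection noise is an idealisation —
real thermograms carry baseline drift, correlated noise and
concentration errors — so passing recovery tests demonstrate estimator
correctness and precision under the stated protocol, not instrument-
level accuracy.

## Melt curves

Thermal-shift curves are fitted with the Boltzmann sigmoid
S(T) = low + (high − low)/(1 + exp((Tm − T)/k)) over the 25–95 °C,
0.2 °C-step scan of the assay protocol, initialised from a
derivative-maximum Tm estimate (moving-average smoothed, window edges
excluded from the argmax so the filter ramp is never mistaken for a
transition); the derivative estimator is also exposed as a model-free
cross-check.  A curve whose amplitude is indistinguishable from its
point-to-point noise, or whose fitted Tm falls outside the scanned
range, raises instead of returning a wrong midpoint.  ΔTm is the fitted
difference sample − reference; the recovery study uses a reference at
50 °C (a representative apo-domain stability; the published work
reports only shifts) and a +12 °C ground-truth shift with 1% amplitude
noise, summarised as the mean over 100 seeded pairs.  The two-state
sigmoid does not model aggregation tails or multi-domain transitions.

## Problem sizes and determinism

The recovery studies use 50 ITC replicates per condition and 100 melt
pairs, sizes at which the medians/means are stable to well inside the
assessment tolerances while the whole acceptance script completes in
seconds.  All randomness flows through `numpy` Generators seeded from
explicit arguments; analysis modules contain no randomness at all, so
identical inputs and configuration yield byte-identical reports.
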