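# Methods

## Scope and model

`radiolyze` analyses molecular-dynamics trajectories of a slow carbon
projectile crossing a liquid-water slab in the adiabatic regime: the
electrons follow the nuclei, so the projectile's kinetic energy goes into
translation, rotation, vibration and — above the dissociation threshold —
into breaking water molecules apart.  The package implements the
post-processing only; it consumes trajectories (positions, velocities,
optional per-atom electron populations) and never integrates forces.
Because first-principles trajectories of this kind are expensive and not
generally available, the package ships an event-kinematic generator that
reproduces the *statistical structure* such trajectories present to the
analysis, together with exact ground-truth event logs.

Units are fixed: Å, fs, eV, unified atomic mass u.  Kinetic energy is
½ m v² × 103.6427 eV/(u·Å²/fs²); the canonical projectile speed unit is
Bohr/fs (1 Bohr = 0.529177 Å).  A 12.011 u carbon at 1, 2, 3, 4 Bohr/fs
carries 174.3, 697.2, 1568.7 and 2788.8 eV, matching the nominal
175 eV / 700 eV / 1.6 keV / 2.8 keV grid to the precision those figures are
printed with.

## Species census

Bonding is geometric: two atoms are neighbours when their minimum-image
distance is within a per-element-pair cutoff, 1.2 Å by default and 0.8 Å for
H–H.  Neighbour search uses a periodic k-d tree; a 27-image brute-force scan
serves as an independent oracle in the tests.  Coordination numbers Z_X(Y)
drive a total labelling (water, hydroxyl, peroxide oxygen, hydronium,
isolated O, isolated H, H₂, bridging H, projectile-bound, other); every atom
carries exactly one label, so label counts conserve atoms exactly.  Two
cutoff presets exist because a blanket 1.2 Å cannot register a peroxide O–O
bond (~1.47 Å): `paper-literal` (the counting convention above) and
`peroxide-capable` (O–O 1.7 Å), the latter being the default for molecular
formula labelling only.  C-atom cutoffs (C–H 1.2 Å, C–O 1.6 Å) are
configurable package choices.

Cumulative fragment *creations* are counted with two guards:

* a **persistence filter** (2 frames): a label change must survive two
  consecutive frames to register, so single-frame grazes of a cutoff sphere
  are ignored;
* a **revisit window** (20 fs): an atom re-entering a label it stably held
  within the window is the same fragment re-emerging (e.g. after the
  projectile's cutoff sphere swept over it), not a new creation.  Genuine
  recombination-and-recreation on longer timescales still counts.

## Event segmentation

The cumulative energy-loss profile L(x) of the projectile is segmented as
follows.  A forward running minimum strips transient excursions that are
later restored (the elastic component of a close collision); what remains is
the net inelastic loss curve.  Frames whose net rise clearly exceeds the
local baseline drift (estimated as the median per-frame rise) are grouped
into discrete events; the baseline drift over the event span is subtracted
from the transfer so a step riding on a continuous ramp is not overcounted.
The stripped excursion height is reported as `peak_height`; excursions with
no net step and a restored fraction above `restoration_fraction` become
`elastic_only` events.  Complement intervals are emitted as continuous
(`vibrational`) segments carrying their share of the loss, so transfers sum
to the terminal loss exactly.

Default thresholds (`EventParams`): a 10 eV minimum net step — chosen so the
smallest dissociative transfer of interest (25 eV) always registers while
vibrational ripple (< 10 eV) never does — a 0.5 restoration fraction, a
5-frame smoothing window, and 2 eV/Å for sustained continuous loss.

Energetics alone cannot distinguish a single from a complete dissociation,
so channels are assigned by cross-checking the census: each hydroxyl
creation within 20 fs / 2 Å votes for a single dissociation, each isolated-O
creation for a complete one; the census wins on conflict, and a creation
with no resolvable profile step (a sub-threshold transfer just before
stopping) is emitted as a census-only event with zero attributed transfer.
Merged events keep sub-event multiplicities.

Trajectory classes follow a fixed priority: stopped → multiple sequential
dissociations → the single dissociative event's channel → continuous loss →
non-dissociative transit.  STOPPED is defined as kinetic energy below 1 eV
sustained for 50 fs inside the slab (no threshold convention exists in the
literature for this; both numbers are configurable).  The exit buffer is
2 Å beyond the slab face.

## Charge states

Hydrogen fragments are labelled from electron populations: ≥ 0.9 e neutral
atom, ≤ 0.4 e cation-like, ~0.7 e molecular-bound (only when the census sees
the H inside a molecule); intermediate populations on unbound H are reported
as `ambiguous`, never silently binned.  Populations are summed over whole
fragments where possible, which suppresses the per-atom arbitrariness of any
population partitioning.  No threshold convention exists for O-bearing
fragments; they are reported with raw populations.

## Ensemble statistics

* **Nuclear stopping power**: mean deposited energy per trajectory divided
  by the slab width (the 15.736 Å water region, not the vacuum), stopped
  projectiles contributing their full initial energy; the standard error of
  the mean is reported.
* **Final-energy histogram**: exit energies binned at 25 eV; stopped and
  truncated runs tallied separately.
* **Production spacing**: Σ(in-slab track length) / Σ(creations) of a
  species, with a trajectory-level bootstrap CI.  Creations are cumulative.
* **Species curves**: per-species mean counts in 1 Å projectile-x bins,
  averaged over trajectories; unvisited bins do not contribute.

## Synthetic track generator

The generator emulates the canonical protocol: 128 rigid waters (gas-phase
monomer geometry, O–O exclusion 2.5 Å, giving the correct ~0.98 g/cm³ in a
15.736 Å cube), a box doubled along x for vacuum, entry points on a uniform
transverse grid, two slab snapshots, 36 × 2 = 72 trajectories per velocity.
The projectile marches along +x; dissociative encounters are a Poisson
process along the path with per-speed mean spacing; each encounter draws a
channel (single/double) and a transfer (uniform 25–50 eV single, 100–150 eV
double, capped at the remaining kinetic energy — a cap stops the track);
binding costs 5.0 eV (first H) and 4.4 eV (second H) are deducted and the
remaining budget becomes fragment kinetic energy, split inversely to mass by
default.  A transient elastic excursion (~30 eV scale) is shown for one
frame after each collision and then restored.  Between encounters a
continuous drain removes energy at a per-speed rate.  The energy ledger
E₀ = E_final + Σ transfers + continuous losses closes to numerical
precision on every track and is written to the `EventLog`.

Fragments are created by relabelling the nearest intact water: departing H
atoms jump just past the coordination cutoff at the event (both bonds of a
complete dissociation break in the same event) and fly along straight
clearance-checked corridors — paths that keep other atoms, previously
settled fragments, and the projectile's line of flight outside the bonding
cutoffs — before resting; H fragments fly `h_mobility_factor` (default 3×)
farther than O/OH, reproducing the qualitative observation that hydrogen
secondaries travel much farther.  Populations, when enabled, are painted:
0.7 e on bound H, 0.95 e on fast fragment H (> 10 eV), 0.3 e on slow
fragment H, nominal values on O and C.

### Calibration

Per-speed defaults are calibrated from the reported production rates by rate
algebra.  At the lowest speed, one H per 5 Å and one OH per 7 Å imply a
dissociative encounter every 5.83 Å with a 5/6 : 1/6 single:double mix
(r_H = r_s + 2 r_d, r_OH = r_s); at the highest, one H per 20 Å and one OH
per 30 Å give 24 Å spacing and a 4/5 : 1/5 mix.  Intermediate speeds are
interpolated (10 Å and 16 Å; 0.82 and 0.81 single fraction).  This is a
calibration of the generator to the reported statistics, not a prediction.

The continuous (sub-dissociative) loss rates are the one genuinely free
knob.  The dissociative rates above deposit *more* energy per Å at low speed
than at high speed, yet nuclear stopping is expected to peak in the keV
range — so the peak must be carried by the non-dissociative channel
(elastic recoils and vibrational excitation), whose per-collision transfer
grows with projectile energy.  Defaults of 1.0 / 3.0 / 7.5 / 8.5 eV/Å at
1–4 Bohr/fs encode that: the resulting four-point stopping curve peaks at
1.6 keV (with 2.8 keV close behind) while the 175 eV ensemble both deposits
less per Å and contains fully stopped tracks.  These rates are a modelling
choice, not a measured quantity.

## Problem sizes

The statistical checks use 200-track ensembles (a 10 × 10 entry grid × 2
snapshots) for spacing and parameter-recovery statistics and 72-track
ensembles per speed for the stopping curve and width comparisons.  The
high-speed spacing ensemble uses a 150 Å slab (400 molecules, lower density)
so each track sees ≥ 5 encounters; spacing statistics depend on the
encounter process, not on the water density.  Frames are sampled so the
projectile moves ~0.75 Å per frame (2 fs stride on the long high-speed
slab, where only the census is consumed).

## Known limitations

* The generator is not force-based: no thermal motion, no recombination
  chemistry, no hydrogen-bond network, no backscattering; waters are rigid
  and static.  Passing tests validate the *analysis pipeline* against a
  controlled statistical model, not the underlying physics.
* At the lowest energy the configured transfer distributions are
  right-truncated by the projectile's remaining energy (a drawn transfer is
  capped and stops the track), so per-channel mean transfers are not
  identifiable there; parameter recovery is therefore checked on the 700 eV
  ensemble, where caps do not occur.
* The intermediate-label suppression (persistence + revisit window) trades a
  small latency in creation detection for robustness against cutoff-grazing
  flicker; both windows are parameters.
* Charge labels for oxygen fragments are deliberately not assigned.
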