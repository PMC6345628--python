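# Methods

## The procedure

`filomap` quantifies where a fluorescently tagged protein of interest (POI)
sits within filopodia — thin actin protrusions 1–5 µm long and 50–200 nm
wide. The analysis chain is:

1. **Per-image contrast normalization.** Each channel of each field of view
   is linearly rescaled so that a robust maximum — the 99.95th intensity
   percentile, standing in for "the brightest cellular structure in the
   field" — maps to 65535 and the 1st percentile (background) maps to 0,
   then clipped to the 16-bit range. The map is monotone and invariant to
   multiplying the raw channel by a constant, which is what makes the fixed
   detection threshold below comparable across images and expression levels.
2. **Line-profile extraction.** Intensity is sampled along user-supplied
   tip-to-base polyline traces at ~1-pixel spacing (the arc length divided
   into `round(length_px)` equal steps so the tip and base are exact sample
   positions), single-pixel width, bilinear interpolation. Filopodium length
   is read directly off the profile: `(n_samples − 1) × spacing`.
3. **Binning.** To make filopodia of different lengths comparable, each
   profile is reduced to 40 bins: sample `i` of `n` (0-based) joins bin
   `floor(i·40/n)`, and each bin takes the median of its samples (an
   even-sized bin takes the mean of the two middle values — a convention;
   any tie-break changes bins by well under a grey level). Bin 1 is the tip.
4. **Detection and categories.** A filopodium is *positive* for the POI
   when at least 3 of the 40 bins reach 10000 on the 0–65535 scale. The
   percentage of positive filopodia across a cohort categorizes the
   protein: ≥ 60 % core, 10–40 % accessory (closed interval), < 10 % absent.
   The gap (40 %, 60 %) is reported as an explicit `intermediate` category
   rather than silently merged into either neighbour.
5. **Enrichment.** Per filopodium, the enrichment ratio is
   `mean(bins 1–6) / mean(bins 7–40)` (tip vs shaft). Cohorts are
   summarized as Tukey statistics (median, quartiles, whiskers at 1.5×IQR);
   a protein is called tip- (shaft-) localized when its median ratio is at
   least two-fold above (below) the median of a plasma-membrane reference
   cohort *and* a two-sided Welch t-test on the log2 ratios is significant
   at α = 0.05. The membrane, not F-actin, anchors the comparison because
   the membrane itself is slightly tip-enriched (the bud at the filopodium
   end). Ratios are computed on positive filopodia only by default (a ratio
   for an absent protein measures noise); filopodia with a zero shaft mean
   are excluded with a logged reason, never epsilon-padded.
6. **The map.** Averaging a cohort's binned profiles (positives and
   negatives alike by default, switchable) gives one 40-bin row; rows
   stack into the filopodia-map heatmap with the tip (bins 1–6)
   demarcated. Raw per-bin means are always written to CSV; per-row max
   normalization is applied for display only and recorded as metadata.
7. **Dynamics.** Tip puncta in time-lapse movies are detected with a
   Laplacian-of-Gaussian filter at σ = diameter/(2√2) for an expected blob
   diameter of 0.8 µm, with subpixel refinement by a quadratic fit to the
   3×3 response neighbourhood, then linked frame-to-frame by exact optimal
   one-to-one assignment (minimum summed squared displacement, solved with
   the Hungarian algorithm) gated at 1 µm. Gap closing is structurally
   disabled: one missed frame terminates a track. Track lifetime,
   `(last − first + 1) × frame interval`, proxies filopodium stability;
   per-cell tables split lifetimes at a configurable 60 s cutoff into
   stable/unstable classes expressed as percentages of the cell's tracks.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `n_bins` | 40 | — | fixed length-free representation |
| `min_positive_bins` / `bin_floor` | 3 / 10000 | bins / intensity | the positive-detection rule |
| `core_min_pct`, `accessory` range | 60, [10, 40] | % | detection-frequency categories |
| tip bins | 1–6 | — | tip/shaft split |
| `fold_threshold` | 2.0 | fold | membrane-referenced localization call |
| `upper_percentile` | 99.95 | % | robust "brightest structure" anchor; resists hot pixels |
| `lower_percentile` | 1.0 | % | background anchor (a choice; the source procedure is silent on the lower bound) |
| `blob_diameter_um` | 0.8 | µm | LoG scale for tip puncta |
| `quality_threshold` | 20 | quality units | see below |
| `max_link_distance_um` | 1.0 | µm | linking gate |
| `frame_interval_s` | 5.0 | s | acquisition cadence |
| `stable_cutoff_s` | 60 | s | lifetime classes (display convention, configurable) |

**Detection quality unit.** Interactive trackers report LoG quality in a
tool-internal unit. Here quality is the scale-normalized LoG peak response
divided by a fixed divisor (447), chosen once so that the reference
synthetic punctum — peak 30000 over background 2000, FWHM 0.6 µm at
0.16 µm pixels — scores ≈ 30 and therefore clears the default threshold of
20 with the same comfortable margin a real tip punctum clears it in
practice. Nothing downstream depends on the absolute unit; the threshold is
fully configurable.

## What the synthetic data emulates — and what it does not

The generator provides ground truth where no raw images exist. It emulates:
filopodia as Gaussian ridges of 150 nm FWHM (mid-range of the physical
50–200 nm width) protruding from a bright cell-body half-plane; a MYO10
channel with an isotropic 300 nm-FWHM punctum at each tip; a POI channel
following one of five localization classes (tip-enriched, shaft-enriched,
shaft-subdomain, uniform, absent), with the protein present in a
`detection_prob` fraction of filopodia; per-image brightness variation
(a dimming-only factor, 0.75–1.0); and camera noise as Poisson shot noise
(gain 4 grey/count) followed by Gaussian read noise (σ = 200 grey).
Default absolute levels — background 1000, shaft 15000, membrane plateau
45000, tip-marker peak 30000 — are conventions chosen to be realistic for
16-bit super-resolution data; no quantitative intensity statistics were
available to calibrate against.

It does **not** simulate optics (no PSF convolution beyond the Gaussian
ridge, no SIM reconstruction artifacts), crossing or bundled filopodia,
photobleaching, or stage drift. Passing tests therefore demonstrate that
the *procedure* is implemented correctly and recovers known ground truth
under realistic contrast and noise — not that the thresholds are optimal
for any particular microscope.

One deliberate realism: because normalization anchors on the brightest
*abundant* structure (the cell body at the 99.95th percentile), POI tips
brighter than that plateau saturate at 65535 after adjustment, compressing
very strong tip enrichments (a ground-truth four-fold tip protein measures
≈ 3.3). This is a property of the normalization procedure itself, not of
the implementation; category and direction calls are unaffected, and the
profile-level generator (which bypasses rendering) recovers folds exactly.

## Numerical choices and degenerate inputs

- Profiles shorter than 40 samples cannot fill every bin; they are
  excluded and logged by default, or (`allow_short`) empty bins are filled
  by linear interpolation and the result flagged.
- Binned values are validated to [0, 65535] with a half-grey tolerance for
  float interpolation residue, then clipped.
- A constant channel cannot be normalized: the error names the channel.
- Welch's t-test (unpaired, two-tailed, unequal variance) is the default
  test, applied to log2 ratios; a Mann-Whitney U alternative sits behind
  the `test` parameter. Multiple-testing correction across proteins is off
  by default (matching the source procedure), with Benjamini–Hochberg
  available via `adjust_p_values`.
- Quartiles use linear interpolation on the sorted sample; whiskers extend
  to the most extreme observations within 1.5×IQR of the quartiles.
- Linking forbids assignments beyond the gate by large-cost masking, then
  drops any residual over-gate pairing, so an infeasible assignment can
  never silently join two distant puncta.
- The profile-level cohort generator rescales a class pattern that would
  exceed 65535 (e.g. a large `tip_fold` on a bright shaft) down into range,
  like an exposure adjustment, so ground-truth ratios are preserved rather
  than clipped.

## Problem sizes used by the test suite

Rule-boundary checks are exhaustive sweeps at the printed values and run in
milliseconds. Recovery suites use cohorts of 200 rendered filopodia per
localization class (eight fields of 25 filopodia each, 1400×1024 px at
0.04 µm/px), 1000 random profiles for the binning oracle, 500-track
lifetime mixtures, and 15–20-spot movies of 30–40 frames — sizes at which
the binomial/sample-mean tolerances in the tests are meaningful while a
full run stays within a few minutes on one CPU.

## Known limitations

- Traces are inputs (drawn by a user or the simulator); the package never
  segments filopodia from still images.
- The simulator's filopodia never cross; real crowded peripheries would
  contaminate single-pixel profiles.
- The tracker has no gap closing, splitting or merging by design; blinking
  puncta fragment into shorter tracks, biasing lifetimes downward.
- The `intermediate` category (detection frequency in (40 %, 60 %)) is a
  reporting convention for a range the source categories leave undefined.
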