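# stapetrack

Automated detection of electrically evoked stapedius reflexes (eSR) in
surgical-microscope video.

During cochlear-implant surgery, electrical stimulation of the implant
electrodes elicits a contraction of the stapedius muscle that is visible as
a sub-millimetre twitch of the stapedius tendon. The lowest stimulation
level that elicits a visible reflex — the eSR threshold (eSRT) — is a
clinically useful proxy for the patient's comfortable loudness level when
fitting the implant. `stapetrack` replaces the surgeon's by-eye judgement
with an image-processing pipeline that decides, per stimulus, whether the
tendon moved, and by how many pixels.

## Pipeline

Given a grayscale frame sequence, two rectangular ROIs (the stapedius
tendon and a reference patch on the cochlear promontory), and a stimulus
log aligned via an audio sync track:

1. **Stabilization** — every frame is registered to the promontory patch by
   normalized cross-correlation, refined to sub-pixel precision
   (translation-only; heartbeat, respiration and microscope vibration are
   global at fixed magnification).
2. **Marker seeding** — maximally stable extremal regions (MSER) inside the
   tendon ROI are summarised by their second-moment ellipses; the ellipse
   centers, thinned by a greedy separation rule, become tracking markers.
3. **Tracking** — pyramidal Kanade–Lucas–Tomasi (KLT) tracking of every
   marker, anchored to its birth template with forward–backward
   validation; global motion is cancelled differentially using markers
   tracked in the reference patch.
4. **Denoising** — each marker trajectory is re-anchored to its pre-stimulus
   rest position, a narrowband heartbeat notch is applied at the rate
   measured from the stabilizer's shift trace, and a Savitzky–Golay filter
   (window 11 frames, polyorder 3) smooths the coordinates while conserving
   the twitch peak.
5. **Decision** — the displacement signal is the per-frame median across
   markers of each marker's distance from rest. A stimulus is an eSR when
   the baseline-corrected peak inside the 0.3 s response window exceeds
   `k = 3` times the noise floor (1.4826 × MAD of the pooled pre-stimulus
   baselines of the raw signal). Sweeping the stimulation level yields the
   eSRT and dynamic range per electrode.

A ground-truthed synthetic-scene generator (`stapetrack.synthetic`) renders
a textured middle-ear field whose tendon twitches with a logistic
amplitude-versus-level law under heartbeat, respiration, camera jitter and
sensor noise — every stage above is validated against its hidden state.
The statistics layer (`stapetrack.stats`) reproduces the study-level
analysis: pairwise rater chi-square tests with Bonferroni correction and
Pearson correlation of stimulus intensity versus motion-vector length.

## Worked example

```python
import stapetrack as st

scene = st.SceneSpec()                       # 160x120 px synthetic field
schedule = st.make_schedule([10, 15, 20, 25, 30, 35])
seq, sync, truth = st.synthesize_sequence(
    scene, schedule, st.NuisanceMotionModel(),
    st.TwitchModel(saturation_amp_px=0.5, threshold_level=20), seed=77,
)
result = st.run_detection(seq, scene.tendon_roi(), scene.reference_patch, schedule)
print(result.to_dataframe()[["level", "detected", "motion_vector_length_px"]])
print(result.esrt_by_electrode()["middle"])
```

```
   level  detected  motion_vector_length_px
0   10.0     False                 0.011643
1   15.0      True                 0.041445
2   20.0      True                 0.245288
3   25.0      True                 0.421771
4   30.0      True                 0.423006
5   35.0      True                 0.399987
SRTEstimate(electrode='middle', esrt_level=15.0, dynamic_range=(15.0, 35.0), monotone=True)
```

The twitch model saturates at 0.5 px with its logistic midpoint at level
20: the level-20 stimulus measures ~0.25 px, higher levels approach the
0.4–0.5 px saturation (minus a few percent of filtering loss), and the
estimated eSRT is 15 — the first tested level whose true amplitude
(0.04 px) clears the detection threshold of about 0.02 px, while the
level-10 twitch (0.003 px) stays under the noise floor.

The same flow is available from the shell:

```bash
stapetrack simulate --seed 7 --out run/
stapetrack detect --frames run/frames --audio run/sync.wav \
    --log run/schedule.csv --rois run/rois.json --out run/out/
stapetrack stats --counts counts.csv
```

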