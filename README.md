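# headdir

Semi-automatic head-direction coding for animal behaviour video.

Behavioural experiments that ask *where was the animal's head pointing on
every frame* — head-turn responses to playback stimuli, orientation
preference, gaze-like measures in species without trackable eyes — need
hundreds of thousands of per-frame annotations. Fully manual coding is
prohibitively slow; fully automatic marker-free tracking is brittle.
`headdir` takes the middle road: a simple, fast, explainable
image-processing chain codes every frame, every decision is written to a
CSV a human can audit, and a replayable manual-override schedule
corrects the frames the algorithm gets wrong. The package also
synchronizes session video with an experiment log via an LED flash,
slices per-trial frame windows, and generates ground-truthed synthetic
scenes so every stage can be validated end to end.

It is aimed at behavioural labs coding overhead footage of a single
animal against a static background — long-bodied species (reptiles,
rodents) and tufted primates each get a dedicated algorithm.

## The algorithm

Per frame `F` with stored empty-scene background `BG`:

1. difference `I = |F − BG|`, greyscale (BT.601 luma);
2. morphological opening, `mExOIter` iterations of 3×3 erosion then
   dilation, removing features narrower than ≈ 2·`mExOIter` + 1 px;
3. binarize at `thParam`; Canny edges; contours filtered by half girth
   (bbox w + h ≥ `contourTh`); MBR over surviving contour points;
4. motion gate `θ_l ≤ sqrt(Σ|Δgrey|/255) < θ_u` against the last motion
   frame — static frames reuse the previous state.

Then, per species:

* **cluster** — k-means over foreground pixels; the cluster nearest
  `hpt = bPos_prev + (cos d, −sin d)·max(MBR_w, MBR_h)` is the head
  cluster; `hPos` = its point nearest `hpt`, `bPos` = the nearest other
  cluster's centroid. Optionally `bPos` comes from a red colour tag
  (HSV in-range centroid) instead.
* **tuft** — the two largest contours are the ear tufts; `bPos` is the
  midpoint of their centres; the ear line rotated 90° gives two
  candidate `hPos`, resolved by the previous heading.

The heading is `hDir = atan2(−(h_y − b_y), h_x − b_x)` ∈ (−180°, 180°],
counterclockwise from image-east (image-up = +90°). Jumps beyond `degTh`
are rejected and the previous state held. Output rows carry `mHPos`
(explicit manual input on this frame) and `mHD` (direction was manual,
including continuous-manual mode) so coder effort is measurable.

## Worked example

Generate a 10-frame synthetic blob-chain scene, code it, and check the
LED synchronizer on a planted session:

```sh
$ headdir synth cluster --outdir scene --seed 4 --n-frames 10
wrote cluster fixture to scene

$ head -3 scene/truth.csv
frame,hPosX,hPosY,bPosX,bPosY,hDir
1,209.416,144.881,219.222,118.654,-110.500
2,208.283,147.013,219.224,121.239,-113.000

$ headdir analyze --frames scene --species cluster --params params.toml \
    --init-hpos 209.416,144.881 --init-bpos 219.222,118.654 --out session.csv
10 frames coded, 0 manual, 0 continuous, 0 fallbacks

$ head -3 session.csv
Frame-index,hPosX,hPosY,mHPos,bPosX,bPosY,hDir,mHD
1,209,145,False,219,119,-111,False
2,209,147,False,219,121,-112,False

$ headdir synth led --outdir led --seed 2 --duration 2
$ headdir sync --frames led --led-roi 4,4,16,12 --threshold 50 --fps 100
session start frame: 38
delta_ms: 370.0

$ headdir eval --truth scene/truth.csv --coded session.csv --out report.json
median max-pairwise difference: 0.75 deg
```

Reading the output: the coded frame 1 `(209, 145) → (219, 119)` is the
planted truth rounded to pixels, and its heading −111° differs from the
planted −110.5° only by rounding. The LED was planted to switch on
370 ms into the video at 100 FPS, i.e. frame 38 — the synchronizer
recovers both exactly. The final line is the median per-frame circular
difference between the coded session and the planted truth.

`params.toml` holds the seven per-species keys:

```toml
mExOIter = 1
thParam = 60
contourTh = 10
motionTh = [0.5, 10000.0]
degTh = 40.0
hdLineLen = 30
k = 4
```

Manual corrections go in an overrides CSV
(`frame_index,hPosX,hPosY,bPosX,bPosY,continuous,continuous_off`) passed
as `--overrides`; trial slicing is `headdir extract` with a session log
of `timestamp_ms,label[,detail]` lines. Video files are not read or
written directly — decode to frames and encode overlays with e.g.
`ffmpeg -i session.mp4 f%06d.jpg` / `ffmpeg -i f%06d.png overlay.mp4`.

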