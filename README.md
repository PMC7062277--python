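# drivehunt

Movement responses of GPS-collared red deer (*Cervus elaphus*) to drive
hunts, as a tested, reusable Python pipeline for movement ecologists and
wildlife managers.

Drive hunts — beaters and dogs sweeping a delimited area toward a line of
stationary shooters — disturb game far beyond the animals actually shot.
Understanding how deer respond matters both for hunting efficiency and for
"hunting-for-fear" management that aims to push deer off sensitive areas.
The pipeline characterizes the response in two phases:

* **Immediate phase** (during the roughly hour-long drive): each monitored
  deer present inside the hunted area at hunt start is a *hunting event*,
  classified **fleeing** if any fix during the drive falls outside the
  area polygon (the deer crossed the shooting line) and **staying**
  otherwise. Per event the pipeline computes maximum speed, sinuosity
  (mean cosine of turning angles: 1 = straight, 0 = Brownian, negative =
  back-tracking) and the cumulative 2-minute step distance DistI.
* **Delayed phase** (to the first 08:00 dawn and the days after): the
  cumulative hourly step distance DistD, net-displacement profiles over
  the five days around the hunt split into day/night periods, and censored
  **return times** — from the flight out of the area to the first fix back
  inside, against a reversed-time pre-hunt control spell, both censored at
  144 h and summarized by Kaplan–Meier curves.

Site familiarity enters through a fixed-kernel utilization distribution
(UD): the annual home range is split into ten nested isopleth bands and a
hunted area *j* of animal *i* scores

```
Fam_ij = iso(0-10)_ij * 1.0 + iso(10-20)_ij * 0.9 + ... + iso(90-95)_ij * 0.15
```

where `iso(x1-x2)_ij` is the fraction of the hunted area inside each band;
Fam is 1 in the home-range core and 0 outside the 95% home range.

Two mixed-effects models carry the inference, each with a per-individual
random intercept u_i ~ N(0, sigma_u^2):

```
log(Dist_i) = mu + a*Bush_i + b*Fam_i + c*Dogs_i + d*Beat_i + r*Shot_i + u_i + e_i
logit P(ShortReturn_i) = mu + a*Hunt_i + b*Fam_i + c*Hunt_i*Fam_i + u_i
```

with Bush the dense-understorey fraction of the area, Dogs/Beat the dog and
beater densities per hectare, Shot the gunshot count, Hunt the post-hunt
vs control condition and ShortReturn the 72-h return dichotomy. The linear
model is fitted by REML, the logistic one by Gauss–Hermite maximum
likelihood; both report estimates with 95% and 75% intervals.

Because no raw telemetry is distributed, the package ships a first-class
synthetic generator (`drivehunt.simulate`) reproducing the study design —
14 hinds with ~561 ha home ranges, 23 hunt days of 4–6 drives over
47–201 ha areas, dual GPS duty cycles (2-min fixes on hunt days, hourly
otherwise) with 82 %/86 % fix success and 5.8 m location error, a 68 %
flee probability and return-lag distributions with 34 h / 17 h medians —
with ground-truth labels for every stage.

## Worked example

`examples/` holds one short script per capability. Detecting and
classifying events, then comparing the groups
(`python examples/02_movement_metrics.py`):

```
median movement metrics per immediate-response group:
                speed_max_kmh  sinuosity  dist_immediate_m  dist_delayed_m
classification
fleeing                 17.57       0.12           2273.97         4488.66
staying                  6.68      -0.26            933.14         3636.97

immediate distances, staying vs fleeing: t = -19.28, df = 118, p = 2.8e-38
delayed distances,   staying vs fleeing: t = -5.54, df = 118, p = 1.9e-07
```

Fleeing deer run fast and straight and cover more than twice the staying
deer's distance during the drive itself (strongly negative t), while by
the first dawn the delayed distances of the two groups are far closer —
staying deer leave too, just later. The other scripts cover population
simulation and file round-trips (`01`), the familiarity index (`03`),
Kaplan–Meier return times (`04`, medians ≈ 34 h post-hunt vs ≈ 17 h
control) and the two mixed models with interval-covered truth (`05`).

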