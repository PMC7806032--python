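# perchsense

Where should a balancing body carry its inertial sensors?  Birds have, in
addition to the vestibular system in the head, a balance-sensing structure
in the pelvis (the lumbosacral organ), close to the legs that do the
balancing.  `perchsense` quantifies the benefit of such hip-localized
sensing for a body perched on a moving substrate: it simulates a compliant
two-stage mechanical stand-in (platform → legs → hip mass → neck → head
mass) under thousands of random center-out-and-back platform
perturbations, then measures, per sensor site,

* **sensing delay** — the lag of the cross-correlation maximum between
  foot and sensor acceleration;
* **effective stiffness** — from the resonant frequency f of head
  acceleration via K = m f² (with f in Hz this is the physical spring
  constant over (2π)²; it is used comparatively);
* **foot-state reconstruction** — a discrete-time state-space model
  x(k+1) = A x(k) + B u(k), y(k) = C x(k) + D u(k) identified by MOESP
  (Multivariable Output-Error State-sPace) subspace identification, mapping
  hip, head, or fused sensor channels u to the 3-axis foot acceleration y,
  scored by variance accounted for, %VAF = 100·(1 − var(ŷ−y)/var(y));
* **bootstrap statistics** — all estimates are resampled over random
  contiguous windows and reported as median (IQR), with Welch t-tests
  between conditions.

The package is aimed at researchers in comparative biomechanics and
sensorimotor control, and at roboticists weighing distributed inertial
sensing for legged machines.  Real multichannel recordings in the
documented CSV layout can be analyzed with the same estimators.

## Worked example

```python
import perchsense as ps

# one synthetic trial: low-stiffness neck, 10 mm perturbation sphere
rec = ps.run_trial("Trial_LS_10", n_moves=300, seed=7)

for site in ("hip", "head"):
    ds = ps.delay_estimates(rec, site)
    print(f"foot->{site} delays (s): " + ", ".join(f"{d.axis}={d.delay_s:.3f}" for d in ds))

boot = ps.stiffness_bootstrap(rec, m_kg=0.12, n_iter=200, segment_s=30, seed=1)
print(f"stiffness K = m f^2: median {boot.median:.2f} N/m (IQR {boot.q25:.2f}-{boot.q75:.2f})")

for source in ("hip", "head", "fusion"):
    r = ps.estimate_foot_acc(rec, source, window=(0, 40), train_samples=4000, held_out=True)
    print(f"VAF({source}) = {r.pooled_vaf:.1f}%")
```

prints

```
foot->hip delays (s): x=0.019, y=0.018, z=0.015
foot->head delays (s): x=0.106, y=0.104, z=0.099
stiffness K = m f^2: median 0.61 N/m (IQR 0.61-0.75)
VAF(hip) = 67.7%
VAF(head) = 1.6%
VAF(fusion) = 58.4%
```

The hip sensor registers the platform perturbation ~18 ms after the feet,
the head only after ~100 ms — mechanical propagation through the compliant
chain.  The hip-based model reconstructs two thirds of the foot-acceleration
variance out of sample; the head-based model, behind the low-pass of a
compliant neck, reconstructs almost none; and fusing head channels onto hip
channels does not improve on hip alone (the head signal is a filtered,
noisier copy of information the hip already carries).

The core model object follows the statsmodels convention — construct from
data, `fit()`, inspect the results:

```python
res = ps.MOESP(rec.hip[:4000], rec.foot[:4000], order=3, s=10, rate_hz=1000).fit()
print(res.summary())       # order, eigenvalues, singular values, per-channel VAF
res.predict(u_new)         # simulate on new input
res.markov(20)             # impulse-response fingerprint
```

The full eight-trial experiment grid (4 sphere radii × 2 neck stiffnesses),
with all bootstraps, comparison tables and a markdown report:

```sh
perchsense run --out results/ --seed 1 --fast   # scaled-down profile
perchsense report results/
```

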