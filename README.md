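# kapentagyrus

Morphometric species delineation and identification for *Kapentagyrus*
(Monogenea, Dactylogyridae) — the gill-infecting flatworms of African
freshwater pellonuline clupeids (sardines of the tribe Pellonulini).

The fourteen known species of *Kapentagyrus* are morphologically very
similar; telling them apart rests almost entirely on the morphometrics of
the sclerotized haptor: the five standard anchor lengths (total length,
length to notch, inner and outer root length, point length) of the dorsal
and ventral anchor, the branch length and maximum width of the two
transversal bars, the lengths of the seven marginal hook pairs, and the
axial lengths of the copulatory tube and accessory piece of the male
copulatory organ.  Two ratios are especially diagnostic:

- the root proportion of an anchor, inner root length / outer root length;
- the inner root length of an anchor relative to the length of hook pair I.

This package is aimed at parasitologists and taxonomists working with
dactylogyrid sclerite measurements.  It provides:

- **`kapentagyrus.morphometry`** — typed specimen records (µm, missing
  values first-class) and the diagnostic ratio features;
- **`kapentagyrus.reference`** — the per-species summary tables
  (min, mean, max, n per parameter; 12 species profiles, one of which
  carries two host-specific columns) and the 30 host-survey rows
  (172 examined fish) as embedded, versioned JSON fixtures;
- **`kapentagyrus.key`** — the published 13-couplet dichotomous key as an
  executable, traceable decision tree with three-valued semantics for
  missing data and boundary values, a host-aware and a host-free mode, and
  a validator that routes every species' mean measurements through the key
  and enumerates the places where the printed key and the measurement
  tables disagree;
- **`kapentagyrus.parasitology`** — exact prevalence / mean intensity /
  mean abundance arithmetic (intensity is worms per *infected* host);
- **`kapentagyrus.ordination`** — the multivariate protocol: 20
  standardized haptoral parameters (hook pair VII excluded), >50%
  missingness filtering, column-mean imputation, full PCA and non-metric
  multidimensional scaling with multiple seeded starts;
- **`kapentagyrus.simulate` / `kapentagyrus.recovery`** — a
  truncated-normal synthetic-specimen generator moment-matched to the
  printed summaries, with a latent size factor for allometric correlation,
  and a parameter-recovery study (simulate → identify → confusion matrix).

## Worked example

```python
from kapentagyrus import builtin_profiles, builtin_surveys, mean_specimen, identify
from kapentagyrus.parasitology import summarize_infection

profiles = {p.species_name: p for p in builtin_profiles()}

# route the mean measurements of K. sefcae through the key
result = identify(mean_specimen(profiles["Kapentagyrus sefcae"]))
print(sorted(result.candidates))   # ['Kapentagyrus sefcae']
print(result.path)                 # [(1, 'a'), (2, 'a')]
```

The species is resolved in two couplets: its ventral length to notch
(30.0 µm > 24) and dorsal anchor total length (39.0 µm > 31) send it down
the *Odaxothrissa* branch, and its ventral anchor total (45.1 µm > 40) and
inner root (26.0 µm > 22) settle it at the first terminal.

```python
# infection parameters of the O. losera lot from Pool Malebo
losera = next(s for s in builtin_surveys()
              if s.parasite_species == "Kapentagyrus sefcae")
s = summarize_infection(losera)
print(float(s.prevalence), s.mean_intensity_display)   # 1.0 9.5
```

Both examined hosts were infected (worm counts 3 and 16), giving a
prevalence of 1.0 and a mean intensity of 9.5 worms per infected host.

The same operations are available from the shell:

```sh
kapentagyrus export-fixtures --out fixtures.csv   # 13 mean specimens
kapentagyrus identify --input fixtures.csv --trace
kapentagyrus key-validate                         # 4 inconsistent column(s)
kapentagyrus stats                                # total hosts examined: 172
kapentagyrus simulate --species all --n 50 --seed 42 --out synth.csv
kapentagyrus ordinate --input synth.csv --method nmds --seed 42 --out scores.csv
```

`key-validate` deliberately reports four inconsistent profile columns: the
printed key conflicts with the species accounts at couplet 11 (the side from
which the accessory piece loops the copulatory tube), the table means of
*K. boegeri* fall on the wrong side of couplet 10's ratio threshold, and the
single *K. chochamandai* specimen from *Potamothrissa acutirostris*
contradicts couplet 13.  These conflicts are surfaced, never silently
corrected; see `docs/methods.md`.

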