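# rbchain

Karyotype algebra, meiotic multivalent prediction and hybrid-fertility
analysis for Robertsonian chromosomal races of the western house mouse
(*Mus musculus domesticus*).

## The problem

The ancestral house-mouse karyotype is 2n = 40 acrocentrics (19 autosome
pairs plus the sex pair).  Robertsonian (centric) fusions join pairs of
acrocentric autosomes into metacentrics, written `a.b`, and local races
carrying different fusion sets have diverged down to 2n = 22.  When two
such races hybridise, metacentrics that share single arms (monobrachial
homology, e.g. `1.3` and `3.6`) cannot pair as bivalents: pairing arm by
arm forces multivalent **chains** and **rings** at meiosis I, and long
chains disrupt gametogenesis — completely in males, partially in females.
This package implements that reasoning as a tested pipeline for people
studying chromosomal speciation in this system:

* **karyotype** — parse/validate fusion-list karyotypes, derive 2n and
  chromosome inventories;
* **meiosis** — build an F1 complement, form the arm-homology pairing
  graph and classify its components as bivalents, chains or rings;
* **segregation** — enumerate balanced gamete classes (alternate
  segregation), predict backcross karyotype distributions, simulate
  breeding outcomes under a nondisjunction model, and estimate the
  nondisjunction rate from scar/litter data
  (`NondisjunctionModel(...).fit()`);
* **fertility** — Fisher sperm-presence test, covariate-adjusted
  category contrasts with family-cluster permutation inference, litter
  and implantation-scar summaries;
* **preference** — two-male choice trials: preference index
  `P = t_CHHN / (t_CHHN + t_CHBU)`, logit analysis with male-pair
  cluster bootstrap (`PreferenceModel(...).fit()`);
* **synthetic** — generators for colony, fertility and preference tables
  with the statistical structure the analyses assume.

The reference system is the Swiss race pair CHBU (Buchs, 2n = 22;
fusions `1.18 2.5 3.6 4.12 7.15 8.16 9.14 10.17 11.13`) and CHHN
(Hünikon, 2n = 24; fusions `1.3 2.8 4.12 5.7 6.15 9.14 10.11 13.16`),
whose F1 hybrids form a chain of fifteen chromosomes.

## Worked example

```python
>>> import rbchain as rb
>>> cfg = rb.configurations_from_cross(rb.CHBU, rb.CHHN)
>>> cfg.f1_diploid_number
23
>>> for c in cfg.configurations:
...     print(c)
chain[15]: 17-17.10-10.11-11.13-13.16-16.8-8.2-2.5-5.7-7.15-15.6-6.3-3.1-1.18-18
bivalent(4.12)
bivalent(9.14)
bivalent(19)
>>> gametes = rb.enumerate_balanced_gametes(cfg)
>>> [g.haploid_count for g in gametes]
[11, 12]
>>> rb.backcross_karyotype_distribution(gametes, rb.CHHN)
{23: 0.5, 24: 0.5}
```

The hybrid carries one long chain (printed arm by arm; the string is
orientation-invariant under `chain_strings_equal`), the two shared
metacentrics `4.12`/`9.14` and chromosome 19 as ordinary bivalents, plus
the sex bivalent.  Alternate segregation of the chain yields exactly two
balanced gamete classes — the two parental haploid sets — so backcrossing
an F1 female to a CHHN male is expected to give half hybrid-karyotype
(2n = 23) and half CHHN-karyotype (2n = 24) offspring.

The same from the shell:

```sh
rbchain hybridize --mother CHBU --father CHHN
rbchain segregate --mother CHBU --father CHHN --mate CHHN
rbchain simulate --rate 0.82 --females 31 --seed 1 --out records.csv
rbchain generate --outdir data --seed 1
rbchain analyze-fertility --males data/males.csv --females data/females.csv --out report.json
rbchain analyze-preference data/trials.csv --out pref.json
```

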