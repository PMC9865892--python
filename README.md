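# lamellipid

Analysis toolkit for distinguishing **multilamellar (ML)** from
**unilamellar (UL)** charged-lipid membrane systems, combining

* **trajectory analyses** of solvated bilayers — area per lipid, mass density
  profiles, P–P membrane thickness, deuterium order parameters (−S_CD),
  radial distribution functions, hydration-shell assignment, interfacial
  water orientation (cosθ distributions, distance-resolved and cumulative
  profiles, dipole tilt vs z), geometric hydrogen-bond detection with
  per-moiety classification, cation contacts, and Einstein-relation
  diffusion (3-D for water, in-plane for lipids);
* **thermotropic analyses** of melting data — Savitzky–Golay smoothing,
  baseline correction, bilinear decomposition of temperature-dependent
  spectra (**D** = **CS**ᵀ + **E** via truncated SVD), single/double
  Boltzmann fitting with R²/χ², DSC onset/maximum/minor-event extraction,
  FTIR-style band maxima, and fluctuation-based mechanics (heat capacity,
  isothermal area compressibility, bending modulus);
* a **synthetic-data module** that builds UL/ML bilayer pseudo-trajectories
  (122 DPPS + 6 DPPG pseudo-lipids, 64 per leaflet, auto-neutralized by 128
  monovalent cations, 6400 or 2781 3-site waters) and melting curves with
  *known ground truth*, so every analysis has a parameter-recovery test
  without external data.

Internal units are nm / ps / amu / kJ·mol⁻¹; converters (e.g. cm² s⁻¹ for
diffusion coefficients) live at the I/O boundaries.

## Command line

```bash
# synthesize a preset system (structure + trajectory + ground-truth JSON)
lamellipid synth bilayer --preset UL35 --seed 1 --frames 25 -o ul35
lamellipid synth spectra --transition 51.5,0.6,-0.6 --transition 53.3,0.5,-0.8 -o spectra.csv
lamellipid synth dsc --peak 52.4,10,0.5 -o dsc.csv

# analyze a trajectory (the plain-text container written above)
lamellipid structure ul35.traj.txt -o tables/
lamellipid water     ul35.traj.txt -o tables/
lamellipid hbonds    ul35.traj.txt -o tables/

# melting-curve decomposition + Boltzmann fit
lamellipid melt spectra.csv --components 1 --fit double -o fit.json

# end-to-end pipeline from a YAML config, then a UL-vs-ML comparison
lamellipid run config.yml
lamellipid compare ul/report.json ml/report.json -o comparison.csv
```

A minimal `config.yml`:

```yaml
preset: UL35        # UL35 | UL65 | ML35 | ML65
seed: 1
n_frames: 25
out_dir: out/ul35
analyses: [structure, water, hbonds]
```

Presets differ only in the water slab (6400 waters, z ≈ 9.4–11.2 nm for UL;
2781 waters, z ≈ 6.5–7.5 nm for ML) and in their ground-truth geometry,
chain order and diffusion coefficients.

## Formats

* Single-frame structures: GRO and PDB (read/write, via MDAnalysis);
  orthorhombic boxes only.
* Multi-frame trajectories: a documented plain-text container
  (`#LAMELLIPID-TRAJ v1` header, atom table, then per-frame time/box header
  and nm coordinates) — see `lamellipid.traj_model.write_trajectory`.
* Spectra: CSV with a wavelength column and one column per temperature.
* DSC: two-column CSV (temperature °C, heat flow).
* All analysis tables: tidy CSV with a `# key: value` metadata header.

## Layout

```
src/lamellipid/
  traj_model.py         data model, GRO/PDB + trajectory I/O, periodic geometry
  synthetic_data.py     UL/ML bilayer and melting-data generators (ground truth)
  membrane_structure.py APL, density profiles, thickness, -S_CD, lateral diffusion
  interfacial_water.py  RDF, shells, water orientation, dipole tilt, 3-D diffusion
  hbond_contacts.py     hydrogen-bond detection/classification, ion contacts
  melting_curves.py     smoothing, baseline, SVD decomposition, Boltzmann/DSC fits,
                        fluctuation mechanics
  cli_reports.py        pipeline orchestration, comparison tables
  cli.py                click CLI (`lamellipid`)
tests/                  unit + property + acceptance suites
scripts/acceptance.py   acceptance report generator
```
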