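# Formula provenance

The four native formulas are implemented from their published equation
chains. Several of them exist in multiple published revisions; this file
records exactly which variant `iolbench.formulas` computes, so results can
be compared against other implementations.

## Shared conventions

- Keratometric diopters ↔ corneal radius: `r_mm = 1000·(n_k − 1)/K` with
  `n_k = 1.3375` (Lenstar-style keratometric index; configurable in
  `derive_features` and `haigis_refraction`).
- Aqueous/vitreous refractive index in every vergence chain: `n = 1.336`.
- Vertex distance default 12 mm; with `vertex_mm = 0` all formulas return
  the corneal-plane refraction.
- All formulas are inverted analytically for the *implanted* power: they
  return the predicted spectacle-plane spherical-equivalent refraction.

## SRK/T

Variant: the corrected-axial-length revision with the corneal-height clamp.

- Corrected AL: `LCOR = AL` for `AL ≤ 24.2`, else
  `LCOR = −3.446 + 1.715·AL − 0.0237·AL²`.
- Corneal width `Cw = −5.41 + 0.58412·LCOR + 0.098·K`.
- Corneal height `H = r − sqrt(r² − Cw²/4)`, with the square-root argument
  clamped at 0 (the published "Cw²/4 > r²" rule).
- ACD constant from the A-constant: `ACDconst = 0.62467·A − 68.747`;
  `ELP = H + ACDconst − 3.336`.
- Retinal thickness `0.65696 − 0.02029·AL` added to AL for the optical
  axial length; vergence constants `na = 1.336`, `nc − 1 = 0.333`.

## Hoffer Q

Variant: the published personalized-ACD formula with its errata, tangent
arguments in **degrees**.

- AL clamped to `[18.5, 31]` mm inside the ELP expression.
- `M = +1, G = 28` for `AL ≤ 23`; `M = −1, G = 23.5` otherwise.
- `ELP = pACD + 0.3·(AL − 23.5) + tan²K + 0.1·M·(23.5 − AL)²·tan(0.1·(G − AL)²) − 0.99166`.
- Power/refraction relation
  `P = 1336/(AL − C − 0.05) − 1.336/(1.336/(K + R) − (C + 0.05)/1000)`
  solved for the corneal-plane refraction `R`, then vertexed out.

## Holladay 1

- `AG = AL·12.5/23.45`, capped at 13.5 mm.
- Anatomical ACD `= 0.56 + r − sqrt(r² − AG²/4)` (clamped square root);
  `ELP = aACD + SF` with the surgeon factor SF.
- Optical axial length `AL + 0.2` mm; vergence constants `na = 1.336`,
  `nc − 1 = 1/3`.

## Haigis

- `ELP = a0 + a1·ACD + a2·AL` (single-constant mode: a1 = 0.4, a2 = 0.1
  fixed; only a0 optimized).
- Corneal power recomputed from the radius with the formula's fictitious
  corneal index 1.3315: `Dc = 331.5/r_mm`.
- Thin-lens chain `P = n/(L − d) − n/(n/z − d)` (distances in metres,
  `z = Dc + corneal-plane refraction`) inverted for the refraction.

## A-constant conversions

Standard published linear maps, used to seed all formulas from a single
configured A-constant (`convert_a_constant`, coefficients overridable):

| target | slope | intercept |
|---|---|---|
| Hoffer Q pACD | 0.58357 | −63.896 |
| Holladay 1 SF | 0.5663 | −65.60 |
| SRK/T ACD-const | 0.62467 | −68.747 |
| Haigis a0 (a1=0.4, a2=0.1) | 0.62467 | −72.434 |
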