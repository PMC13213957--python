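# Default carbohydrate HET-code vocabulary.
#
# The list is operational, not chemical: a ligand group counts as a
# carbohydrate iff its residue name is in this set.  It is seeded with the
# pyranose monosaccharides that dominate the curated structural databases
# (glucose, galactose, mannose, xylose, fucose, sialic acid, GlcNAc,
# GalNAc, KDO) and is user-extensible: pass your own YAML with a
# `sugar_codes` list to extend or replace it.
sugar_codes:
  - GLC   # alpha-D-glucose
  - BGC   # beta-D-glucose
  - GAL   # beta-D-galactose
  - GLA   # alpha-D-galactose
  - MAN   # alpha-D-mannose
  - BMA   # beta-D-mannose
  - XYS   # alpha-D-xylose
  - XYP   # beta-D-xylose
  - FUC   # alpha-L-fucose
  - FUL   # beta-L-fucose
  - SIA   # N-acetylneuraminic (sialic) acid
  - NAG   # N-acetyl-D-glucosamine
  - NGA   # N-acetyl-D-galactosamine
  - KDO   # 3-deoxy-D-manno-oct-2-ulosonic acid

# Distance cutoffs in angstroms.
contact_cutoff: 4.2     # residue heavy atom to ligand atom -> binding label
covalent_cutoff: 1.8    # ligand atom to protein heavy atom -> covalent attachment
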