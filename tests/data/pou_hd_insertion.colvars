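# bias protocol: pou_hd_insertion
colvar {
    name hd_inner_ramp_cv
    distanceInv {
        exponent 100
        group1 { tf:POU_HD:CA }
        group2 { dna:inner_gyre:P }
    }
}
harmonic {
    name hd_inner_ramp
    colvars hd_inner_ramp_cv
    forceConstant 10
    centers 5
    targetCenters 15
    targetDuration 250 ns
}
colvar {
    name hd_outer_ramp_cv
    distanceInv {
        exponent 100
        group1 { tf:POU_HD:CA }
        group2 { dna:outer_gyre_3p:P }
    }
}
harmonic {
    name hd_outer_ramp
    colvars hd_outer_ramp_cv
    forceConstant 10
    centers 32
    targetCenters 12
    targetDuration 250 ns
}
colvar {
    name hd_ldna_ramp_cv
    distanceInv {
        exponent 100
        group1 { tf:POU_HD:CA }
        group2 { dna:linker_3p:P }
    }
}
harmonic {
    name hd_ldna_ramp
    colvars hd_ldna_ramp_cv
    forceConstant 10
    centers 58
    targetCenters 28
    targetDuration 250 ns
}
colvar {
    name tails_outer_dmin_wall_cv
    distanceInv {
        exponent 100
        group1 { tails:H3-A+H2A-A:CA }
        group2 { dna:outer_gyre_3p:P }
    }
}
harmonicWalls {
    name tails_outer_dmin_wall
    colvars tails_outer_dmin_wall_cv
    lowerWalls 30
    forceConstant 10
}
colvar {
    name tails_outer_coord_wall_cv
    coordNum {
        cutoff 4
        expNumer 6
        expDenom 12
        group1 { tails:H3-A+H2A-A:CA }
        group2 { dna:outer_gyre_3p:P }
    }
}
harmonicWalls {
    name tails_outer_coord_wall
    colvars tails_outer_coord_wall_cv
    upperWalls 0
    forceConstant 10
}
colvar {
    name intergyre_dmin_wall_cv
    distanceInv {
        exponent 100
        group1 { dna:inner_gyre:P }
        group2 { dna:outer_gyre_3p:P }
    }
}
harmonicWalls {
    name intergyre_dmin_wall
    colvars intergyre_dmin_wall_cv
    lowerWalls 20
    forceConstant 10
}
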