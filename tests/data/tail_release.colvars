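# bias protocol: tail_release
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
    lowerWalls 12
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
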