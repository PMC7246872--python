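"""Flat reference transliteration of the ISO 7933:2004 minute loop.

Written deliberately in the style of the standard's published program — one
flat loop, inline constants, single-letter style variables — to serve as an
independent oracle for the structured engine in ``heatstrain.phs``.  It
shares no code with the package.
"""

import math


def phs_reference(
    ta,
    tr,
    pa,
    va,
    met,
    wme=0.0,
    clo=0.5,
    imst=0.38,
    weight=70.0,
    height=1.75,
    posture=2,
    accl=100,
    drink=1,
    walksp=0.0,
    theta=None,
    duration=480,
    d_frac=0.05,
):
    """Run the minute loop; met and wme in W/m2, pa in kPa, clo in clo.

    ``walksp=None`` selects the speed-deduced-from-metabolism branch;
    ``theta=None`` the unknown-wind-direction branch.  Returns a dict with
    per-minute rectal temperature and cumulative water loss plus the DLEs.
    """
    adu = 0.202 * weight**0.425 * height**0.725
    spheat = 57.83 * weight / adu

    tre = 36.8
    tcr = 36.8
    tsk = 34.1
    tcreq = 36.8
    tsktcrwg = 0.3
    swp = 0.0
    swtotg = 0.0

    dmax = d_frac * weight * 1000.0
    dlimtre = 0
    dlimloss = 0

    constteq = math.exp(-1.0 / 10.0)
    consttsk = math.exp(-1.0 / 3.0)
    constsw = math.exp(-1.0 / 10.0)

    # effective radiating area
    ardu = {1: 0.7, 2: 0.77, 3: 0.67}[posture]

    # walking speed / relative velocity
    if walksp is None:
        walksp = 0.0052 * (met - 58.0)
        if walksp > 0.7:
            walksp = 0.7
        if walksp < 0.0:
            walksp = 0.0
        var = va
    elif theta is not None:
        var = abs(va - walksp * math.cos(math.pi * theta / 180.0))
    else:
        var = va if va > walksp else walksp
    if var < 0.15:
        var = 0.15

    # static then dynamic clothing
    fcl = 1.0 + 0.3 * clo
    iclst = clo * 0.155
    iast = 0.111
    itotst = iclst + iast / fcl
    vaux = var if var < 3.0 else 3.0
    waux = walksp if walksp < 1.5 else 1.5
    corcl = 1.044 * math.exp((0.066 * vaux - 0.398) * vaux + (0.094 * waux - 0.378) * waux)
    if corcl > 1.0:
        corcl = 1.0
    coria = math.exp((0.047 * vaux - 0.472) * vaux + (0.117 * waux - 0.342) * waux)
    if coria > 1.0:
        coria = 1.0
    cortot = corcl
    if clo <= 0.6:
        cortot = ((0.6 - clo) * coria + clo * corcl) / 0.6
    itotdyn = itotst * cortot
    iadyn = coria * iast
    icldyn = itotdyn - iadyn / fcl
    if icldyn < 1e-6:
        icldyn = 1e-6
    core = (2.6 * cortot - 6.5) * cortot + 4.9
    imdyn = imst * core
    if imdyn > 0.9:
        imdyn = 0.9
    rtdyn = itotdyn / imdyn / 16.7

    # maximum sweat rate and wettedness
    swmax = (met - 32.0) * adu
    if swmax > 400.0:
        swmax = 400.0
    if swmax < 250.0:
        swmax = 250.0
    if accl >= 50:
        swmax = swmax * 1.25
    wmax = 1.0 if accl >= 50 else 0.85

    tre_series = []
    water_series = []

    for minute in range(1, duration + 1):
        tsk0 = tsk
        tre0 = tre
        tcr0 = tcr
        tcreq0 = tcreq
        tsktcrwg0 = tsktcrwg
        swp0 = swp

        # equilibrium core temperature
        tcreqm = 0.0036 * met + 36.6
        tcreq = tcreq0 * constteq + tcreqm * (1.0 - constteq)
        dstoreq = spheat * (tcreq - tcreq0) * (1.0 - tsktcrwg0)

        # skin temperature
        tskeqcl = (
            12.165 + 0.02017 * ta + 0.04361 * tr + 0.19354 * pa - 0.25315 * va
            + 0.005346 * met + 0.51274 * tre0
        )
        tskeqnu = 7.191 + 0.064 * ta + 0.061 * tr + 0.198 * pa - 0.348 * va + 0.616 * tre0
        if clo >= 0.6:
            tskeq = tskeqcl
        elif clo <= 0.2:
            tskeq = tskeqnu
        else:
            tskeq = tskeqnu + 2.5 * (tskeqcl - tskeqnu) * (clo - 0.2)
        tsk = tsk0 * consttsk + tskeq * (1.0 - consttsk)
        psk = 0.6105 * math.exp(17.27 * tsk / (tsk + 237.3))

        # convection and radiation through clothing
        z = 3.5 + 5.2 * var
        if var > 1.0:
            z = 8.7 * var**0.6
        hcdyn = 2.38 * abs(tsk - ta) ** 0.25
        if z > hcdyn:
            hcdyn = z
        auxr = 5.67e-8 * ardu
        fclr = 0.97  # no reflective clothing in the reference
        tcl = tr + 0.1
        while True:
            hr = fclr * auxr * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4) / (tcl - tr)
            tcl1 = (fcl * (hcdyn * ta + hr * tr) + tsk / icldyn) / (
                fcl * (hcdyn + hr) + 1.0 / icldyn
            )
            if abs(tcl - tcl1) <= 0.001:
                break
            tcl = (tcl + tcl1) / 2.0
        conv = fcl * hcdyn * (tcl - ta)
        rad = fcl * hr * (tcl - tr)

        # respiration
        texp = 28.56 + 0.115 * ta + 0.641 * pa
        cres = 0.001516 * met * (texp - ta)
        eres = 0.00127 * met * (59.34 + 0.53 * ta - 11.63 * pa)

        emax = (psk - pa) / rtdyn
        ereq = met - dstoreq - wme - cres - eres - conv - rad

        # required sweat rate
        if ereq <= 0.0:
            ereq = 0.0
            swreq = 0.0
        elif emax <= 0.0:
            emax = 0.0
            swreq = swmax
        else:
            wreq = ereq / emax
            if wreq >= 1.7:
                swreq = swmax
            else:
                eveff = 1.0 - wreq * wreq / 2.0
                if wreq > 1.0:
                    eveff = (2.0 - wreq) * (2.0 - wreq) / 2.0
                swreq = ereq / eveff
                if swreq > swmax:
                    swreq = swmax

        # predicted sweat rate and evaporation
        swp = swp0 * constsw + swreq * (1.0 - constsw)
        if swp <= 0.0:
            swp = 0.0
            ep = 0.0
        else:
            k = emax / swp
            wp = 1.0
            if k >= 0.5:
                wp = -k + math.sqrt(k * k + 2.0)
            if wp > wmax:
                wp = wmax
            ep = wp * emax

        # heat storage and core temperature
        dstorage = ereq - ep + dstoreq
        tcr1 = tcr0
        while True:
            tsktcrwg = 0.3 - 0.09 * (tcr1 - 36.8)
            if tsktcrwg > 0.3:
                tsktcrwg = 0.3
            if tsktcrwg < 0.1:
                tsktcrwg = 0.1
            tcr = dstorage / spheat + tsk0 * tsktcrwg0 / 2.0 - tsk * tsktcrwg / 2.0
            tcr = (tcr + tcr0 * (1.0 - tsktcrwg0 / 2.0)) / (1.0 - tsktcrwg / 2.0)
            if abs(tcr - tcr1) <= 0.001:
                break
            tcr1 = (tcr1 + tcr) / 2.0

        tre = tre0 + (2.0 * tcr - 1.962 * tre0 - 1.31) / 9.0

        swtotg = swtotg + (swp + eres) * 2.67 / 1.8 / 60.0 * adu

        if dlimtre == 0 and tre >= 38.0:
            dlimtre = minute
        if dlimloss == 0 and swtotg >= dmax:
            dlimloss = minute

        tre_series.append(tre)
        water_series.append(swtotg)

    return {
        "t_re": tre_series,
        "water_g": water_series,
        "dle_tre": dlimtre if dlimtre else duration,
        "dle_water": dlimloss if dlimloss else duration,
    }
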