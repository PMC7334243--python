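<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="203.000" height="1958.667" viewBox="0 0 203.000 1958.667">
<title>Idiogram test</title>
<g id="axis" stroke="#000000" stroke-width="1">
<line x1="41.400" y1="46.000" x2="41.400" y2="1912.667"/>
<line x1="37.400" y1="1912.667" x2="41.400" y2="1912.667"/>
<text x="34.400" y="1915.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">0</text>
<line x1="37.400" y1="1856.667" x2="41.400" y2="1856.667"/>
<text x="34.400" y="1859.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">2</text>
<line x1="37.400" y1="1800.667" x2="41.400" y2="1800.667"/>
<text x="34.400" y="1803.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">4</text>
<line x1="37.400" y1="1744.667" x2="41.400" y2="1744.667"/>
<text x="34.400" y="1747.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">6</text>
<line x1="37.400" y1="1688.667" x2="41.400" y2="1688.667"/>
<text x="34.400" y="1691.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">8</text>
<line x1="37.400" y1="1632.667" x2="41.400" y2="1632.667"/>
<text x="34.400" y="1635.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">10</text>
<line x1="37.400" y1="1576.667" x2="41.400" y2="1576.667"/>
<text x="34.400" y="1579.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">12</text>
<line x1="37.400" y1="1520.667" x2="41.400" y2="1520.667"/>
<text x="34.400" y="1523.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">14</text>
<line x1="37.400" y1="1464.667" x2="41.400" y2="1464.667"/>
<text x="34.400" y="1467.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">16</text>
<line x1="37.400" y1="1408.667" x2="41.400" y2="1408.667"/>
<text x="34.400" y="1411.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">18</text>
<line x1="37.400" y1="1352.667" x2="41.400" y2="1352.667"/>
<text x="34.400" y="1355.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">20</text>
<line x1="37.400" y1="1296.667" x2="41.400" y2="1296.667"/>
<text x="34.400" y="1299.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">22</text>
<line x1="37.400" y1="1240.667" x2="41.400" y2="1240.667"/>
<text x="34.400" y="1243.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">24</text>
<line x1="37.400" y1="1184.667" x2="41.400" y2="1184.667"/>
<text x="34.400" y="1187.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">26</text>
<line x1="37.400" y1="1128.667" x2="41.400" y2="1128.667"/>
<text x="34.400" y="1131.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">28</text>
<line x1="37.400" y1="1072.667" x2="41.400" y2="1072.667"/>
<text x="34.400" y="1075.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">30</text>
<line x1="37.400" y1="1016.667" x2="41.400" y2="1016.667"/>
<text x="34.400" y="1019.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">32</text>
<line x1="37.400" y1="960.667" x2="41.400" y2="960.667"/>
<text x="34.400" y="963.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">34</text>
<line x1="37.400" y1="904.667" x2="41.400" y2="904.667"/>
<text x="34.400" y="907.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">36</text>
<line x1="37.400" y1="848.667" x2="41.400" y2="848.667"/>
<text x="34.400" y="851.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">38</text>
<line x1="37.400" y1="792.667" x2="41.400" y2="792.667"/>
<text x="34.400" y="795.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">40</text>
<line x1="37.400" y1="736.667" x2="41.400" y2="736.667"/>
<text x="34.400" y="739.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">42</text>
<line x1="37.400" y1="680.667" x2="41.400" y2="680.667"/>
<text x="34.400" y="683.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">44</text>
<line x1="37.400" y1="624.667" x2="41.400" y2="624.667"/>
<text x="34.400" y="627.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">46</text>
<line x1="37.400" y1="568.667" x2="41.400" y2="568.667"/>
<text x="34.400" y="571.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">48</text>
<line x1="37.400" y1="512.667" x2="41.400" y2="512.667"/>
<text x="34.400" y="515.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">50</text>
<line x1="37.400" y1="456.667" x2="41.400" y2="456.667"/>
<text x="34.400" y="459.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">52</text>
<line x1="37.400" y1="400.667" x2="41.400" y2="400.667"/>
<text x="34.400" y="403.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">54</text>
<line x1="37.400" y1="344.667" x2="41.400" y2="344.667"/>
<text x="34.400" y="347.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">56</text>
<line x1="37.400" y1="288.667" x2="41.400" y2="288.667"/>
<text x="34.400" y="291.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">58</text>
<line x1="37.400" y1="232.667" x2="41.400" y2="232.667"/>
<text x="34.400" y="235.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">60</text>
<line x1="37.400" y1="176.667" x2="41.400" y2="176.667"/>
<text x="34.400" y="179.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">62</text>
<line x1="37.400" y1="120.667" x2="41.400" y2="120.667"/>
<text x="34.400" y="123.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">64</text>
<line x1="37.400" y1="64.667" x2="41.400" y2="64.667"/>
<text x="34.400" y="67.667" font-size="9" text-anchor="end" stroke="none" fill="#000000">66</text>
</g>
<g id="pair-1">
<text x="82.000" y="38.000" font-size="11" text-anchor="middle" fill="#000000">1</text>
<rect x="69.000" y="46.000" width="26.000" height="745.167" fill="#e8e8e8" rx="3.000" stroke="#444444" stroke-width="1"/>
<rect x="69.000" y="794.167" width="26.000" height="1118.500" fill="#e8e8e8" rx="3.000" stroke="#444444" stroke-width="1"/>
<rect x="70.000" y="46.000" width="24.000" height="560.000" fill="#2ca02c"/><!--45S-->
</g>
<g id="pair-2">
<text x="126.000" y="38.000" font-size="11" text-anchor="middle" fill="#000000">2</text>
<rect x="113.000" y="979.333" width="26.000" height="371.833" fill="#e8e8e8" rx="3.000" stroke="#444444" stroke-width="1"/>
<rect x="113.000" y="1354.167" width="26.000" height="558.500" fill="#e8e8e8" rx="3.000" stroke="#444444" stroke-width="1"/>
<rect x="114.000" y="1352.667" width="24.000" height="168.000" fill="#d62728"/><!--CPD-->
</g>
</svg>
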